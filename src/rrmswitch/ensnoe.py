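"""NOE upper-bound validation of conformer and trajectory ensembles.

The NOE between two protons reports an effective distance dominated by the
closest approaches in the ensemble; the appropriate ensemble statistic is
the r^-6 weighted average

    r_eff = ( < r^-6 > )^(-1/6)

taken over frames (and, for degenerate proton groups, over the equivalent
pairs). Each restraint's r_eff is compared against its experimental upper
bound; violations are binned in 0.1 A bands as is conventional for
structure-quality tables.

Restraints are read from CYANA-style ``.upl`` lines

    <resnum> <resname> <atom> <resnum> <resname> <atom> <bound>

or an equivalent TSV. Pseudo-atom selectors (QB, QD, QG2, ...) are expanded
to the matching protons present in the model rather than corrected
additively on the bound.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

from .structrot import StructureEnsemble, _find_residue

VIOLATION_BINS = ((0.1, 0.2), (0.2, 0.3), (0.3, 0.4))


@dataclass(frozen=True)
class AtomSelector:
    resnum: int
    resname: str
    atom: str


@dataclass(frozen=True)
class NOERestraint:
    """One upper-bound distance restraint between two (pseudo-)atom groups."""

    a: AtomSelector
    b: AtomSelector
    upper_bound: float
    pseudo_correction: float = 0.0
    restraint_id: str = ""

    def __post_init__(self) -> None:
        if self.upper_bound <= 0:
            raise ValueError("upper bound must be positive")


def parse_upl(text_or_path: str | Path) -> list[NOERestraint]:
    """Parse CYANA .upl restraint lines (text or file path)."""
    if isinstance(text_or_path, Path) or (
            "\n" not in str(text_or_path) and Path(str(text_or_path)).exists()):
        text = Path(text_or_path).read_text()
    else:
        text = str(text_or_path)
    restraints = []
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.split("#")[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) < 7:
            raise ValueError(f"malformed upl line {lineno}: {line!r}")
        restraints.append(NOERestraint(
            a=AtomSelector(int(parts[0]), parts[1], parts[2]),
            b=AtomSelector(int(parts[3]), parts[4], parts[5]),
            upper_bound=float(parts[6]),
            restraint_id=f"{parts[0]}{parts[1]}.{parts[2]}-"
                         f"{parts[3]}{parts[4]}.{parts[5]}"))
    return restraints


def r6_average(distances) -> float:
    """Ensemble-averaged effective NOE distance, (mean r^-6)^(-1/6)."""
    r = np.asarray(distances, dtype=float)
    if r.size == 0:
        raise ValueError("empty distance series")
    if np.any(r <= 0):
        raise ValueError("distances must be positive")
    return float(np.mean(r ** -6.0) ** (-1.0 / 6.0))


def resolve_pseudoatoms(selector: AtomSelector,
                        model: gemmi.Model) -> list[str]:
    """Expand a selector to the concrete atom names it covers in the model.

    Explicit atoms resolve to themselves. ``Q``-prefixed pseudo-atoms cover
    all protons sharing the position code (QB -> HB2/HB3/..., QD1 ->
    HD11/HD12/HD13); doubled codes (QQD) cover both branches (HD1*, HD2*).
    """
    residue = _find_residue(model, selector.resnum)
    if residue is None:
        raise KeyError(f"residue {selector.resnum} {selector.resname} "
                       "not found in model")
    names = [atom.name for atom in residue]
    if selector.atom in names:
        return [selector.atom]
    if not selector.atom.startswith("Q"):
        raise KeyError(f"atom {selector.atom} not found in residue "
                       f"{selector.resnum} {selector.resname}")
    if selector.atom.startswith("QQ"):
        code = selector.atom[2:]
        prefixes = [f"H{code}1", f"H{code}2", f"H{code}3"]
        matched = [n for n in names
                   if any(n.startswith(p) for p in prefixes)]
    else:
        code = selector.atom[1:]
        matched = [n for n in names if n.startswith(f"H{code}")
                   and n != f"H{code}"] or [n for n in names
                                            if n == f"H{code}"]
    if not matched:
        raise KeyError(f"pseudo-atom {selector.atom} matches no protons in "
                       f"residue {selector.resnum} {selector.resname}")
    return matched


def _positions(model: gemmi.Model, resnum: int,
               atom_names: list[str]) -> np.ndarray:
    residue = _find_residue(model, resnum)
    out = []
    for name in atom_names:
        atom = residue.find_atom(name, "*")
        if atom is None:
            raise KeyError(f"atom {name} missing from residue {resnum}")
        out.append([atom.pos.x, atom.pos.y, atom.pos.z])
    return np.asarray(out)


def effective_distance(restraint: NOERestraint, model: gemmi.Model) -> float:
    """r^-6 combined distance between the two (expanded) proton groups."""
    names_a = resolve_pseudoatoms(restraint.a, model)
    names_b = resolve_pseudoatoms(restraint.b, model)
    pos_a = _positions(model, restraint.a.resnum, names_a)
    pos_b = _positions(model, restraint.b.resnum, names_b)
    d = np.linalg.norm(pos_a[:, None, :] - pos_b[None, :, :], axis=2).ravel()
    return r6_average(d)


@dataclass
class ViolationRecord:
    restraint_id: str
    r6_distance: float
    upper_bound: float
    violation: float
    n_frames: int


@dataclass
class ViolationReport:
    records: list[ViolationRecord]
    bin_counts: dict[str, int] = field(default_factory=dict)
    n_violated: int = 0
    max_violation: float = 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "restraint_id": r.restraint_id, "r6_A": r.r6_distance,
            "bound_A": r.upper_bound, "violation_A": r.violation,
            "n_frames": r.n_frames} for r in self.records])


def _bin_label(lo: float, hi: float | None) -> str:
    return f"{lo:.1f}-{hi:.1f}" if hi is not None else f">{lo:.1f}"


def _bin_violations(violations: list[float]) -> dict[str, int]:
    counts = {_bin_label(lo, hi): 0 for lo, hi in VIOLATION_BINS}
    counts[_bin_label(0.4, None)] = 0
    for v in violations:
        if v <= 0:
            continue
        for lo, hi in VIOLATION_BINS:
            if lo <= v < hi:
                counts[_bin_label(lo, hi)] += 1
                break
        else:
            if v >= 0.4:
                counts[_bin_label(0.4, None)] += 1
    return counts


def evaluate(restraints: list[NOERestraint],
             distances: dict[str, np.ndarray] | None = None,
             ensemble: StructureEnsemble | None = None,
             tolerance: float = 0.0) -> ViolationReport:
    """Check restraints against an ensemble or pre-extracted distances.

    ``distances`` maps restraint_id to a per-frame distance array (e.g.,
    exported from a trajectory tool); alternatively ``ensemble`` computes
    per-model effective distances internally. The per-restraint violation is
    ``max(0, r_eff - bound - tolerance)`` and the summary bins violations in
    the conventional 0.1 A bands.
    """
    if (distances is None) == (ensemble is None):
        raise ValueError("provide exactly one of distances or ensemble")
    records = []
    for restraint in restraints:
        if distances is not None:
            if restraint.restraint_id not in distances:
                raise KeyError(f"no distance series for restraint "
                               f"{restraint.restraint_id}")
            series = np.asarray(distances[restraint.restraint_id], dtype=float)
            r_eff = r6_average(series)
            n_frames = series.size
        else:
            per_model = [effective_distance(restraint, m)
                         for m in ensemble.models]
            r_eff = r6_average(per_model)
            n_frames = len(per_model)
        violation = max(0.0, r_eff - restraint.upper_bound - tolerance)
        records.append(ViolationRecord(
            restraint_id=restraint.restraint_id, r6_distance=r_eff,
            upper_bound=restraint.upper_bound, violation=violation,
            n_frames=n_frames))
    violations = [r.violation for r in records]
    return ViolationReport(
        records=records,
        bin_counts=_bin_violations(violations),
        n_violated=sum(v > 0 for v in violations),
        max_violation=max(violations) if violations else 0.0)


def read_distance_table(path: str | Path) -> dict[str, np.ndarray]:
    """Read a TSV (frame, restraint_id, r) into per-restraint series."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"frame", "restraint_id", "r"}
    if not required <= set(df.columns):
        raise ValueError(f"distance table needs columns {sorted(required)}")
    return {str(rid): grp.sort_values("frame")["r"].to_numpy()
            for rid, grp in df.groupby("restraint_id")}
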