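"""Structure-based chi1 rotamer analysis of multi-conformer ensembles.

Computes the chi1 dihedral (N-CA-CB-CG) of aromatic residues from
coordinates, bins it into the staggered rotamers, classifies the RNA-binding
surface of an RRM as UP or DOWN from the joint rotamer signature of six
interface aromatics, and computes ensemble RMSD-to-mean statistics by
iterative least-squares superposition.

The UP/DOWN templates describe the two conformations of the binding surface
of the third RRM of CELF proteins: in the UP state the interface aromatics
point away from the beta-sheet (the low-affinity, AU-binding surface), in
the DOWN state key side chains flip toward it (the high-affinity, UG-binding
surface). Template residue numbers use the construct numbering of the
domain (416-508); an offset maps them onto deposited coordinate numbering
and is auto-detected from the residue types when not given.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .rotamerfit import ROTAMER_CENTERS

AROMATIC_RESIDUES = {"PHE", "TYR", "HIS", "TRP"}

#: joint chi1 rotamer signatures of the six interface aromatics, in construct
#: numbering; gauche+ is the staggered state at chi1 = -60 degrees
UP_TEMPLATE = {426: "gplus", 428: "gplus", 429: "gplus",
               455: "gplus", 466: "trans", 468: "trans"}
DOWN_TEMPLATE = {426: "trans", 428: "trans", 429: "gplus",
                 455: "trans", 466: "gminus", 468: "gplus"}

#: residue types expected at the template positions, used for offset detection
TEMPLATE_RESTYPES = {426: "PHE", 428: "TYR", 429: "HIS",
                     455: "PHE", 466: "PHE", 468: "PHE"}

BACKBONE_ATOMS = {"N", "CA", "C", "O"}


@dataclass
class StructureEnsemble:
    """An ordered bundle of conformers sharing one atom inventory."""

    models: list[gemmi.Model]
    source: str = ""
    # owning gemmi.Structure, retained so the model references stay valid
    structure: object = None

    def __len__(self) -> int:
        return len(self.models)

    @classmethod
    def from_pdb(cls, path_or_text: str | Path) -> "StructureEnsemble":
        return read_ensemble(path_or_text)


def read_ensemble(path_or_text: str | Path) -> StructureEnsemble:
    """Parse a (multi-model) PDB file or PDB-format string.

    Alternate locations are reduced to the highest-occupancy conformer;
    files carrying insertion codes are rejected. A file without MODEL
    records yields a single-model ensemble.
    """
    if isinstance(path_or_text, Path) or "\n" not in str(path_or_text):
        structure = gemmi.read_pdb(str(path_or_text))
        source = str(path_or_text)
    else:
        structure = gemmi.read_pdb_string(str(path_or_text))
        source = "<string>"
    structure.remove_alternative_conformations()  # keeps highest occupancy first
    for model in structure:
        for chain in model:
            for residue in chain:
                if residue.seqid.icode not in ("", " "):
                    raise ValueError(
                        f"insertion code {residue.seqid.icode!r} at residue "
                        f"{residue.seqid.num} not supported")
    return StructureEnsemble(models=list(structure), source=source,
                             structure=structure)


def _find_atom(model: gemmi.Model, resnum: int, atom_name: str,
               chain: str | None = None) -> gemmi.Atom | None:
    for ch in model:
        if chain is not None and ch.name != chain:
            continue
        for residue in ch:
            if residue.seqid.num == resnum:
                atom = residue.find_atom(atom_name, "*")
                if atom is not None:
                    return atom
    return None


def _find_residue(model: gemmi.Model, resnum: int,
                  chain: str | None = None) -> gemmi.Residue | None:
    for ch in model:
        if chain is not None and ch.name != chain:
            continue
        for residue in ch:
            if residue.seqid.num == resnum:
                return residue
    return None


def dihedral(a: np.ndarray, b: np.ndarray, c: np.ndarray,
             d: np.ndarray) -> float:
    """Signed dihedral angle a-b-c-d in degrees, range (-180, 180].

    Positive sign means the far bond c-d appears rotated clockwise from
    a-b when sighting along b->c (the standard biomolecular convention).
    """
    b0 = np.asarray(a) - np.asarray(b)
    b1 = np.asarray(c) - np.asarray(b)
    b2 = np.asarray(d) - np.asarray(c)
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - (b0 @ b1) * b1
    w = b2 - (b2 @ b1) * b1
    x = float(v @ w)
    y = float(np.cross(b1, v) @ w)
    angle = math.degrees(math.atan2(y, x))
    return 180.0 if angle <= -180.0 else angle


def chi1(model: gemmi.Model, resnum: int, chain: str | None = None) -> float | None:
    """chi1 (N-CA-CB-CG) of a residue in degrees; None when not computable.

    The fourth atom is CG, which is the single gamma carbon of the aromatic
    residue classes this package analyses (Phe/Tyr/His/Trp).
    """
    residue = _find_residue(model, resnum, chain)
    if residue is None:
        return None
    coords = []
    for name in ("N", "CA", "CB", "CG"):
        atom = residue.find_atom(name, "*")
        if atom is None:
            return None
        coords.append(np.array([atom.pos.x, atom.pos.y, atom.pos.z]))
    return dihedral(*coords)


@dataclass(frozen=True)
class RotamerAssignment:
    """A chi1 value binned to the nearest staggered rotamer centre."""

    residue: int | None
    chi1: float
    rotamer: str
    distance_to_center: float
    tie: bool = False


def _circular_distance(a: float, b: float) -> float:
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)


def assign_rotamer(chi1_deg: float, residue: int | None = None) -> RotamerAssignment:
    """Bin a chi1 angle to the nearest of 180, -60, +60 degrees.

    Exact ties (60 degrees from two centres) are broken toward trans and
    flagged.
    """
    if not np.isfinite(chi1_deg):
        raise ValueError("chi1 must be finite")
    dists = {name: _circular_distance(chi1_deg, center)
             for name, center in ROTAMER_CENTERS.items()}
    best = min(dists.values())
    winners = [n for n, d in dists.items() if abs(d - best) < 1e-9]
    tie = len(winners) > 1
    if tie and "trans" in winners:
        choice = "trans"
    else:
        choice = winners[0]
    return RotamerAssignment(residue=residue, chi1=chi1_deg, rotamer=choice,
                             distance_to_center=best, tie=tie)


@dataclass
class StateCall:
    """UP/DOWN/MIXED call for one conformer against the surface templates."""

    model_index: int
    call: str
    n_match_up: int
    n_match_down: int
    per_residue: dict[int, dict] = field(default_factory=dict)


def detect_offset(model: gemmi.Model,
                  template_restypes: dict[int, str] = TEMPLATE_RESTYPES,
                  chain: str | None = None) -> int:
    """Find the numbering offset mapping template numbers onto the model.

    Tries every offset implied by a residue whose type matches a template
    position and keeps the one under which all template residues resolve to
    the expected types.
    """
    model_residues = {}
    for ch in model:
        if chain is not None and ch.name != chain:
            continue
        for residue in ch:
            model_residues[residue.seqid.num] = residue.name
    candidates = set()
    for tnum, ttype in template_restypes.items():
        for rnum, rtype in model_residues.items():
            if rtype == ttype:
                candidates.add(rnum - tnum)
    for offset in sorted(candidates, key=abs):
        if all(model_residues.get(tnum + offset) == ttype
               for tnum, ttype in template_restypes.items()):
            return offset
    raise ValueError("could not detect a numbering offset matching the "
                     "six template residue types")


def classify_state(model: gemmi.Model, model_index: int = 0,
                   offset: int | None = None,
                   up_template: dict[int, str] = UP_TEMPLATE,
                   down_template: dict[int, str] = DOWN_TEMPLATE,
                   chain: str | None = None) -> StateCall:
    """Classify one conformer's binding surface as UP, DOWN or MIXED.

    The call is UP (DOWN) only when every template residue's chi1 rotamer
    matches the UP (DOWN) signature exactly; anything else is MIXED.
    """
    if offset is None:
        offset = detect_offset(model, chain=chain)
    per_residue: dict[int, dict] = {}
    n_up = n_down = 0
    for tnum in sorted(up_template):
        resnum = tnum + offset
        angle = chi1(model, resnum, chain)
        if angle is None:
            raise ValueError(f"template residue {tnum} (model number {resnum}) "
                             "not resolvable: missing residue or chi1 atoms")
        assignment = assign_rotamer(angle, residue=resnum)
        match_up = assignment.rotamer == up_template[tnum]
        match_down = assignment.rotamer == down_template[tnum]
        n_up += match_up
        n_down += match_down
        per_residue[tnum] = {"chi1": angle, "rotamer": assignment.rotamer,
                             "match_up": match_up, "match_down": match_down}
    n_total = len(up_template)
    if n_up == n_total:
        call = "UP"
    elif n_down == n_total:
        call = "DOWN"
    else:
        call = "MIXED"
    return StateCall(model_index=model_index, call=call,
                     n_match_up=n_up, n_match_down=n_down,
                     per_residue=per_residue)


def classify_ensemble(ensemble: StructureEnsemble, offset: int | None = None,
                      chain: str | None = None) -> tuple[list[StateCall], dict]:
    """Per-model state calls plus the ensemble fraction in each state."""
    if offset is None:
        offset = detect_offset(ensemble.models[0], chain=chain)
    calls = [classify_state(m, i, offset=offset, chain=chain)
             for i, m in enumerate(ensemble.models)]
    n = len(calls)
    summary = {state: sum(c.call == state for c in calls) / n
               for state in ("UP", "DOWN", "MIXED")}
    summary["n_models"] = n
    summary["offset"] = offset
    return calls, summary


# ---------------------------------------------------------------------------
# ensemble RMSD to the mean structure


def select_atoms(model: gemmi.Model,
                 residue_ranges: list[tuple[int, int]] | None = None,
                 mode: str = "heavy",
                 chains: list[str] | None = None) -> list[tuple[str, int, str]]:
    """List (chain, resnum, atom name) keys for an RMSD selection.

    ``mode`` is "heavy" (all non-hydrogen atoms) or "backbone" (N, CA, C, O).
    """
    if mode not in ("heavy", "backbone"):
        raise ValueError("mode must be 'heavy' or 'backbone'")
    keys = []
    for ch in model:
        if chains is not None and ch.name not in chains:
            continue
        for residue in ch:
            num = residue.seqid.num
            if residue_ranges is not None and not any(
                    lo <= num <= hi for lo, hi in residue_ranges):
                continue
            for atom in residue:
                if atom.is_hydrogen():
                    continue
                if mode == "backbone" and atom.name not in BACKBONE_ATOMS:
                    continue
                keys.append((ch.name, num, atom.name))
    return keys


def _coords_for_keys(model: gemmi.Model,
                     keys: list[tuple[str, int, str]]) -> np.ndarray:
    coords = np.empty((len(keys), 3))
    index = {}
    for ch in model:
        for residue in ch:
            for atom in residue:
                index[(ch.name, residue.seqid.num, atom.name)] = (
                    atom.pos.x, atom.pos.y, atom.pos.z)
    for i, key in enumerate(keys):
        if key not in index:
            raise KeyError(f"selection atom {key} missing from a model")
        coords[i] = index[key]
    return coords


def _superpose(mobile: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Least-squares (Kabsch) superposition of mobile onto target."""
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    rot, _ = Rotation.align_vectors(target - tc, mobile - mc)
    return rot.apply(mobile - mc) + tc


@dataclass
class EnsembleRMSD:
    """Per-model RMSD to the converged mean structure over a selection."""

    per_model: np.ndarray
    mean: float
    sd: float
    n_atoms: int
    n_iterations: int


def ensemble_rmsd(ensemble: StructureEnsemble,
                  residue_ranges: list[tuple[int, int]] | None = None,
                  mode: str = "heavy",
                  chains: list[str] | None = None,
                  tol: float = 1e-6, max_iter: int = 100) -> EnsembleRMSD:
    """RMSD of each conformer to the ensemble mean structure.

    All conformers are superposed onto the current mean coordinates by
    unweighted least-squares rotation/translation over the selection, the
    mean is recomputed, and the cycle repeats until the mean moves by less
    than ``tol`` Angstrom (RMS displacement).
    """
    if len(ensemble) < 2:
        raise ValueError("ensemble RMSD needs at least two models")
    keys = select_atoms(ensemble.models[0], residue_ranges, mode, chains)
    if not keys:
        raise ValueError("empty atom selection")
    coords = np.stack([_coords_for_keys(m, keys) for m in ensemble.models])

    mean = coords[0].copy()
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        aligned = np.stack([_superpose(c, mean) for c in coords])
        new_mean = aligned.mean(axis=0)
        shift = float(np.sqrt(np.mean(np.sum((new_mean - mean) ** 2, axis=1))))
        mean = new_mean
        coords = aligned
        if shift < tol:
            break
    per_model = np.sqrt(np.mean(np.sum((coords - mean) ** 2, axis=2), axis=1))
    return EnsembleRMSD(per_model=per_model, mean=float(per_model.mean()),
                        sd=float(per_model.std(ddof=1)), n_atoms=len(keys),
                        n_iterations=n_iter)


# ---------------------------------------------------------------------------
# rotamer occupancies over models or trajectory frames


def rotamer_occupancy_ensemble(ensemble: StructureEnsemble, resnum: int,
                               chain: str | None = None) -> dict[str, float]:
    """Fraction of conformers in each staggered rotamer for one residue."""
    angles = []
    for model in ensemble.models:
        angle = chi1(model, resnum, chain)
        if angle is not None:
            angles.append(angle)
    if not angles:
        raise ValueError(f"chi1 not computable for residue {resnum} in any model")
    return _occupancy_from_angles(angles)


def rotamer_occupancy_table(frame_table: pd.DataFrame,
                            residue: int | None = None) -> dict:
    """Occupancies from a TSV-style frame table (frame, residue, chi1_deg)."""
    required = {"frame", "residue", "chi1_deg"}
    if not required <= set(frame_table.columns):
        raise ValueError(f"frame table needs columns {sorted(required)}")
    out = {}
    for resnum, grp in frame_table.groupby("residue"):
        if residue is not None and resnum != residue:
            continue
        out[int(resnum)] = _occupancy_from_angles(grp["chi1_deg"].to_numpy())
    if residue is not None:
        return out[int(residue)]
    return out


def _occupancy_from_angles(angles) -> dict[str, float]:
    counts = {"trans": 0, "gplus": 0, "gminus": 0}
    for angle in angles:
        counts[assign_rotamer(float(angle)).rotamer] += 1
    n = len(angles)
    return {name: counts[name] / n for name in counts}


def chi1_table(ensemble: StructureEnsemble, residues: list[int],
               chain: str | None = None) -> pd.DataFrame:
    """Per-model chi1 and rotamer for the requested residues."""
    rows = []
    for i, model in enumerate(ensemble.models):
        for resnum in residues:
            angle = chi1(model, resnum, chain)
            rows.append({
                "model": i, "residue": resnum,
                "chi1_deg": angle if angle is not None else np.nan,
                "rotamer": (assign_rotamer(angle).rotamer
                            if angle is not None else "not computable"),
            })
    return pd.DataFrame(rows)
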