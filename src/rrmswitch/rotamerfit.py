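"""Three-site chi1 rotamer population fitting from 3J scalar couplings.

A side chain hopping between the three staggered chi1 states trans (180
degrees), gauche+ (-60) and gauche- (+60) averages its 3J NCgamma and
3J C'Cgamma couplings linearly over the state populations:

    J_calc(type) = p_t * J_t(type) + p_g+ * J_g+(type) + p_g- * J_g-(type)
    1 = p_t + p_g+ + p_g-

with per-type Karplus expectation values J_t, J_g+, J_g- for the fully
populated states. Populations are recovered by minimising

    chi2 = sum_types ((J_calc - J_exp) / sigma_Jexp)^2

over the probability simplex. With both coupling types the 2x3 design
augmented with the normalisation row is generically rank 3 and the fit is
unique; with a single type the problem is underdetermined and the full
solution interval per population is reported instead of a point estimate.

Note on naming: the rotamer labels follow the physical chemistry convention
used for these couplings, gauche+ at chi1 = -60 degrees and gauche- at +60.
Set ``iupac_labels=True`` where offered to emit the opposite convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import linprog, minimize

from .jcoupling import COUPLING_TYPES, CouplingMeasurement

ROTAMER_NAMES = ("trans", "gplus", "gminus")

#: chi1 centres (degrees) of the staggered states, aligned with ROTAMER_NAMES
ROTAMER_CENTERS = {"trans": 180.0, "gplus": -60.0, "gminus": 60.0}

#: floor applied to replicate sigmas so degenerate agreement cannot produce
#: infinite chi2 weights (Hz)
SIGMA_FLOOR = 0.05


@dataclass(frozen=True)
class KarplusTable:
    """Expected couplings (Hz) for fully populated staggered states.

    One (J_t, J_g+, J_g-) triple per coupling type.
    """

    values: dict[str, tuple[float, float, float]]

    def row(self, coupling_type: str) -> np.ndarray:
        try:
            return np.asarray(self.values[coupling_type], dtype=float)
        except KeyError:
            raise KeyError(f"no Karplus values for coupling type {coupling_type!r}")

    def design_rank(self) -> int:
        """Rank of the coupling rows stacked with the normalisation row."""
        rows = [self.row(t) for t in sorted(self.values)]
        rows.append(np.ones(3))
        return int(np.linalg.matrix_rank(np.vstack(rows)))

    @classmethod
    def from_file(cls, path: str | Path) -> "KarplusTable":
        """Read a key-value config: lines ``<type> <J_t> <J_g+> <J_g->``."""
        values: dict[str, tuple[float, float, float]] = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(f"malformed Karplus line: {line!r}")
            values[parts[0]] = (float(parts[1]), float(parts[2]), float(parts[3]))
        unknown = set(values) - set(COUPLING_TYPES)
        if unknown:
            raise ValueError(f"unknown coupling types in Karplus file: {sorted(unknown)}")
        return cls(values)


def default_karplus() -> KarplusTable:
    """Load the packaged default aromatic-residue Karplus values."""
    from importlib.resources import files

    return KarplusTable.from_file(files("rrmswitch") / "data" / "karplus_aromatic.txt")


@dataclass
class RotamerPopulations:
    """Populations of the three staggered chi1 rotamers for one residue.

    ``intervals`` is filled only for underdetermined fits and gives, per
    rotamer, the (min, max) population compatible with the data.
    """

    residue: int | None
    p_trans: float
    p_gplus: float
    p_gminus: float
    chi2: float = 0.0
    underdetermined: bool = False
    intervals: dict[str, tuple[float, float]] | None = None
    status: str = "ok"
    _extra: dict = field(default_factory=dict, repr=False)

    @property
    def as_array(self) -> np.ndarray:
        return np.array([self.p_trans, self.p_gplus, self.p_gminus])

    @property
    def major(self) -> str:
        return ROTAMER_NAMES[int(np.argmax(self.as_array))]

    def __post_init__(self) -> None:
        p = self.as_array
        if self.status == "ok":
            if np.any(p < -1e-9) or abs(p.sum() - 1.0) > 1e-9:
                raise ValueError(f"populations not on the simplex: {p}")


def predict_J(pops: RotamerPopulations | np.ndarray, karplus: KarplusTable,
              coupling_type: str) -> float:
    """Population-weighted Karplus mixture coupling in Hz."""
    p = pops.as_array if isinstance(pops, RotamerPopulations) else np.asarray(pops)
    return float(p @ karplus.row(coupling_type))


def _chi2(p: np.ndarray, rows: np.ndarray, J_exp: np.ndarray,
          sigma: np.ndarray) -> float:
    return float(np.sum(((rows @ p - J_exp) / sigma) ** 2))


def _population_intervals(rows: np.ndarray, J_target: np.ndarray,
                          ) -> dict[str, tuple[float, float]]:
    """Min/max of each population on {p >= 0, sum p = 1, rows @ p = J_target}.

    Solved as small linear programs; the equality is relaxed by a hair to
    absorb floating-point noise from the preceding chi2 fit.
    """
    eps = 1e-6
    A_ub = np.vstack([rows, -rows])
    b_ub = np.concatenate([J_target + eps, -(J_target - eps)])
    A_eq = np.ones((1, 3))
    b_eq = [1.0]
    intervals = {}
    for i, name in enumerate(ROTAMER_NAMES):
        c = np.zeros(3)
        c[i] = 1.0
        lo = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
                     bounds=[(0, 1)] * 3)
        hi = linprog(-c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
                     bounds=[(0, 1)] * 3)
        intervals[name] = (
            float(lo.x[i]) if lo.success else 0.0,
            float(hi.x[i]) if hi.success else 1.0,
        )
    return intervals


def fit_populations(measurements: list[CouplingMeasurement],
                    karplus: KarplusTable,
                    sigma_floor: float = SIGMA_FLOOR) -> RotamerPopulations:
    """Fit staggered-rotamer populations for one residue by chi2 minimisation.

    The simplex constraint is hard: the optimiser works in two free
    coordinates (p_trans, p_gplus) with p_gminus eliminated, multi-started
    from the three vertices and the barycentre since the quadratic chi2 can
    attain its constrained minimum on the boundary.
    """
    if not measurements:
        raise ValueError("no coupling measurements supplied")
    residues = {m.residue for m in measurements}
    if len(residues) > 1:
        raise ValueError("measurements span more than one residue")
    residue = measurements[0].residue

    rows = np.vstack([karplus.row(m.coupling_type) for m in measurements])
    J_exp = np.array([m.J for m in measurements])
    sigma = np.maximum(np.array([m.sigma_J for m in measurements]), sigma_floor)

    # rank of couplings + normalisation decides identifiability
    design = np.vstack([rows, np.ones(3)])
    n_types = len({m.coupling_type for m in measurements})
    underdetermined = (n_types < 2) or (np.linalg.matrix_rank(design) < 3)

    def objective(x: np.ndarray) -> float:
        p = np.array([x[0], x[1], 1.0 - x[0] - x[1]])
        return _chi2(p, rows, J_exp, sigma)

    starts = [(1.0, 0.0), (0.0, 1.0), (0.0, 0.0), (1 / 3, 1 / 3)]
    best = None
    for x0 in starts:
        res = minimize(objective, x0, method="SLSQP",
                       bounds=[(0.0, 1.0), (0.0, 1.0)],
                       constraints=[{"type": "ineq",
                                     "fun": lambda x: 1.0 - x[0] - x[1]}],
                       options={"ftol": 1e-14, "maxiter": 200})
        if best is None or res.fun < best.fun:
            best = res
    p = np.array([best.x[0], best.x[1], 1.0 - best.x[0] - best.x[1]])
    p = np.clip(p, 0.0, 1.0)
    p /= p.sum()

    intervals = None
    if underdetermined:
        intervals = _population_intervals(rows, rows @ p)

    return RotamerPopulations(
        residue=residue,
        p_trans=float(p[0]), p_gplus=float(p[1]), p_gminus=float(p[2]),
        chi2=_chi2(p, rows, J_exp, sigma),
        underdetermined=underdetermined,
        intervals=intervals,
    )


def fit_populations_separate(measurements: list[CouplingMeasurement],
                             karplus: KarplusTable,
                             sigma_floor: float = SIGMA_FLOOR,
                             ) -> dict[str, RotamerPopulations]:
    """Fit each coupling type on its own (always underdetermined)."""
    out = {}
    for ctype in sorted({m.coupling_type for m in measurements}):
        sub = [m for m in measurements if m.coupling_type == ctype]
        out[ctype] = fit_populations(sub, karplus, sigma_floor)
    return out


def fit_table(measurements: list[CouplingMeasurement], karplus: KarplusTable,
              residues: list[int] | None = None,
              sigma_floor: float = SIGMA_FLOOR) -> pd.DataFrame:
    """Fit every residue in a coupling table.

    ``residues`` optionally names the full residue set of interest; members
    without any coupling data are reported with status "not determined".
    """
    by_residue: dict[int, list[CouplingMeasurement]] = {}
    for m in measurements:
        by_residue.setdefault(m.residue, []).append(m)
    all_residues = sorted(set(by_residue) | set(residues or []))
    rows = []
    for residue in all_residues:
        if residue not in by_residue:
            rows.append({"residue": residue, "p_trans": np.nan,
                         "p_gplus": np.nan, "p_gminus": np.nan,
                         "chi2": np.nan, "major": "",
                         "underdetermined": False,
                         "status": "not determined"})
            continue
        pops = fit_populations(by_residue[residue], karplus, sigma_floor)
        rows.append({"residue": residue, "p_trans": pops.p_trans,
                     "p_gplus": pops.p_gplus, "p_gminus": pops.p_gminus,
                     "chi2": pops.chi2, "major": pops.major,
                     "underdetermined": pops.underdetermined,
                     "status": "ok"})
    return pd.DataFrame(rows, columns=["residue", "p_trans", "p_gplus",
                                       "p_gminus", "chi2", "major",
                                       "underdetermined", "status"])


def relabel_iupac(name: str) -> str:
    """Swap gauche labels to the IUPAC-style convention (g+ at +60)."""
    return {"gplus": "gminus", "gminus": "gplus"}.get(name, name)


def grid_fit(measurements: list[CouplingMeasurement], karplus: KarplusTable,
             resolution: float = 0.005,
             sigma_floor: float = SIGMA_FLOOR) -> RotamerPopulations:
    """Exhaustive simplex grid search; the slow, assumption-free reference.

    Evaluates chi2 on a regular simplex lattice of the given resolution and
    returns the best lattice point. Used to validate the constrained
    optimiser; accuracy is limited by the lattice spacing.
    """
    rows = np.vstack([karplus.row(m.coupling_type) for m in measurements])
    J_exp = np.array([m.J for m in measurements])
    sigma = np.maximum(np.array([m.sigma_J for m in measurements]), sigma_floor)

    steps = int(round(1.0 / resolution))
    i, j = np.meshgrid(np.arange(steps + 1), np.arange(steps + 1), indexing="ij")
    mask = (i + j) <= steps
    pt = i[mask] / steps
    pg = j[mask] / steps
    P = np.column_stack([pt, pg, 1.0 - pt - pg])  # (n_points, 3)
    resid = (P @ rows.T - J_exp) / sigma
    chi2 = np.sum(resid ** 2, axis=1)
    k = int(np.argmin(chi2))
    return RotamerPopulations(
        residue=measurements[0].residue,
        p_trans=float(P[k, 0]), p_gplus=float(P[k, 1]), p_gminus=float(P[k, 2]),
        chi2=float(chi2[k]),
    )
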