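"""Chemical-shift-perturbation titration analysis for 1:1 protein-ligand binding.

Peak movements in 1H-15N HSQC spectra during a ligand titration are reduced
to a combined amide shift

    dCS_obs = sqrt(dHN^2 + (dN / 6.41)^2)        [ppm]

and fitted, per residue, with the single-site binding isotherm that accounts
explicitly for ligand depletion (no excess-ligand approximation):

    dCS_obs = dCS_max * ((Kd + L0 + c*P0) - sqrt((Kd + L0 + c*P0)^2
                          - 4 * L0 * c * P0)) / (2 * c * P0)

where P0 and L0 are total protein and ligand concentrations, Kd the
dissociation constant, dCS_max the shift of the fully bound state and c a
correction coefficient absorbing systematic error in the protein
concentration. The quotient is exactly the fraction of protein in the
complex, so the same quadratic also answers "how saturated is the protein
at this ratio" (see :func:`fraction_bound`).

Peak positions are assumed to be population-weighted averages of the free
and bound states (fast exchange); series whose shifts are non-monotonic in
ligand beyond the noise level are flagged, not silently fitted.

Units: molar and ppm internally; TSV I/O uses micromolar and ppm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

#: scaling of nitrogen shifts onto the proton scale in the combined metric
NITROGEN_SCALE = 6.41

#: residues whose total shift stays under this (ppm) are excluded as flat
DEFAULT_DCSMAX_THRESHOLD = 0.03

TITRATION_COLUMNS = ["residue", "point_index", "P0_uM", "L0_uM",
                     "dHN_ppm", "dN_ppm"]


def combined_shift(dHN: float | np.ndarray, dN: float | np.ndarray):
    """Combined 1H/15N chemical-shift change in ppm (non-negative)."""
    return np.sqrt(np.asarray(dHN, dtype=float) ** 2
                   + (np.asarray(dN, dtype=float) / NITROGEN_SCALE) ** 2)


def predict(Kd: float, L0, P0, c: float = 1.0, dCS_max: float = 1.0):
    """Depletion-binding isotherm: expected combined shift at a titration point.

    Vectorised over ``L0``/``P0``. Equals ``dCS_max`` times the fraction of
    protein bound, hence lies in [0, dCS_max].
    """
    Kd = float(Kd)
    L0 = np.asarray(L0, dtype=float)
    P0 = np.asarray(P0, dtype=float)
    if Kd <= 0:
        raise ValueError("Kd must be positive")
    if np.any(P0 <= 0) or np.any(L0 < 0) or c <= 0:
        raise ValueError("need P0 > 0, L0 >= 0, c > 0")
    s = Kd + L0 + c * P0
    disc = s ** 2 - 4.0 * L0 * c * P0
    assert np.all(disc >= -1e-12), "negative discriminant: invalid inputs"
    frac = (s - np.sqrt(np.maximum(disc, 0.0))) / (2.0 * c * P0)
    return dCS_max * frac


def fraction_bound(Kd: float, P0, L0):
    """Fraction of total protein in the complex from the mass-balance quadratic.

    This is the saturation check used when choosing protein:ligand ratios
    for structural work on weak complexes.
    """
    return np.clip(predict(Kd, L0, P0, c=1.0, dCS_max=1.0), 0.0, 1.0)


@dataclass
class ResidueFit:
    """Per-residue isotherm fit result."""

    residue: int
    Kd: float | None
    dCS_max: float | None
    Kd_stderr: float | None = None
    dCS_max_stderr: float | None = None
    c: float = 1.0
    c_stderr: float | None = None
    accepted: bool = True
    reason: str = ""
    non_monotonic: bool = False
    n_points: int = 0


@dataclass
class BindingFit:
    """Titration summary: per-residue fits and the averaged Kd."""

    residue_fits: list[ResidueFit]
    average_Kd: float
    sd_Kd: float
    n_resonances: int
    c: float = 1.0
    flags: list[str] = field(default_factory=list)


def _check_monotonic(L0: np.ndarray, dcs: np.ndarray,
                     noise_floor: float) -> bool:
    order = np.argsort(L0)
    d = np.diff(dcs[order])
    return bool(np.any(d < -3.0 * noise_floor))


def fit_residue(L0: np.ndarray, P0: np.ndarray, dHN: np.ndarray,
                dN: np.ndarray, residue: int = 0, c: float | None = 1.0,
                noise_floor: float = 0.005,
                dcsmax_threshold: float = DEFAULT_DCSMAX_THRESHOLD,
                ) -> ResidueFit:
    """Fit (Kd, dCS_max) for one residue's titration series.

    Concentrations in molar. ``c=None`` frees the protein-concentration
    correction (bounds [0.5, 2]); otherwise it is held fixed. Series whose
    maximal shift stays below ``dcsmax_threshold`` are excluded as flat.
    Returns asymptotic standard errors from the fit covariance.
    """
    L0 = np.asarray(L0, dtype=float)
    P0 = np.asarray(P0, dtype=float)
    if len(L0) < 3:
        raise ValueError("need at least 3 titration points")
    dcs = combined_shift(dHN, dN)
    if float(np.max(dcs)) < dcsmax_threshold:
        return ResidueFit(residue=residue, Kd=None, dCS_max=None,
                          accepted=False, reason="flat series",
                          n_points=len(L0))
    non_monotonic = _check_monotonic(L0, dcs, noise_floor)

    Kd0 = max(float(np.median(L0[L0 > 0])), 1e-9)
    dcs0 = float(np.max(dcs)) * 1.2
    if c is None:
        def model(L, Kd, dCS_max, cc):
            return predict(Kd, L, P0, cc, dCS_max)
        p0 = [Kd0, dcs0, 1.0]
        bounds = ([1e-12, 1e-6, 0.5], [1.0, 10.0, 2.0])
    else:
        def model(L, Kd, dCS_max):
            return predict(Kd, L, P0, c, dCS_max)
        p0 = [Kd0, dcs0]
        bounds = ([1e-12, 1e-6], [1.0, 10.0])

    popt, pcov = curve_fit(model, L0, dcs, p0=p0, bounds=bounds,
                           maxfev=20000)
    perr = np.sqrt(np.diag(pcov))
    fit = ResidueFit(residue=residue, Kd=float(popt[0]),
                     dCS_max=float(popt[1]),
                     Kd_stderr=float(perr[0]), dCS_max_stderr=float(perr[1]),
                     c=float(popt[2]) if c is None else float(c),
                     c_stderr=float(perr[2]) if c is None else None,
                     non_monotonic=non_monotonic, n_points=len(L0))
    return fit


def average_Kd(fits: list[ResidueFit],
               dcsmax_threshold: float = DEFAULT_DCSMAX_THRESHOLD,
               max_rel_stderr: float = 1.0) -> BindingFit:
    """Unweighted mean +/- SD of Kd over accepted residues.

    The acceptance rule mirrors common titration practice: a resonance
    contributes when it shifts enough to carry information
    (dCS_max >= threshold) and its Kd is determined to better than
    ``max_rel_stderr`` relative standard error.
    """
    accepted = []
    flags = []
    for fit in fits:
        if fit.Kd is None or fit.dCS_max is None:
            fit.accepted = False
            fit.reason = fit.reason or "no fit"
            continue
        if fit.dCS_max < dcsmax_threshold:
            fit.accepted = False
            fit.reason = "dCS_max below threshold"
            continue
        if (fit.Kd_stderr is not None
                and fit.Kd_stderr > max_rel_stderr * fit.Kd):
            fit.accepted = False
            fit.reason = "Kd standard error too large"
            continue
        fit.accepted = True
        accepted.append(fit)
    if not accepted:
        raise ValueError("no residues pass the acceptance rule")
    kds = np.array([f.Kd for f in accepted])
    sd = float(np.std(kds, ddof=1)) if len(kds) > 1 else 0.0
    if len(kds) == 1:
        flags.append("single accepted resonance: SD undefined, reported as 0")
    return BindingFit(residue_fits=fits, average_Kd=float(np.mean(kds)),
                      sd_Kd=sd, n_resonances=len(accepted),
                      c=accepted[0].c, flags=flags)


def fit_table(df: pd.DataFrame, c: float | None = 1.0,
              noise_floor: float = 0.005,
              dcsmax_threshold: float = DEFAULT_DCSMAX_THRESHOLD,
              max_rel_stderr: float = 1.0) -> BindingFit:
    """Fit every residue in a titration table and average the Kds.

    Expects the TSV schema (residue, point_index, P0_uM, L0_uM, dHN_ppm,
    dN_ppm); concentrations are converted to molar internally.
    """
    missing = set(TITRATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"titration table missing columns: {sorted(missing)}")
    fits = []
    for residue, grp in df.groupby("residue", sort=True):
        grp = grp.sort_values("point_index")
        fits.append(fit_residue(
            L0=grp["L0_uM"].to_numpy() * 1e-6,
            P0=grp["P0_uM"].to_numpy() * 1e-6,
            dHN=grp["dHN_ppm"].to_numpy(),
            dN=grp["dN_ppm"].to_numpy(),
            residue=int(residue), c=c, noise_floor=noise_floor,
            dcsmax_threshold=dcsmax_threshold))
    return average_Kd(fits, dcsmax_threshold, max_rel_stderr)


def read_titration_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def binding_fit_frame(result: BindingFit) -> pd.DataFrame:
    """Per-residue output table (micromolar / ppm units)."""
    rows = []
    for f in result.residue_fits:
        rows.append({
            "residue": f.residue,
            "Kd_uM": f.Kd * 1e6 if f.Kd is not None else np.nan,
            "dCSmax_ppm": f.dCS_max if f.dCS_max is not None else np.nan,
            "Kd_stderr_uM": (f.Kd_stderr * 1e6
                             if f.Kd_stderr is not None else np.nan),
            "accepted": f.accepted,
            "reason": f.reason,
            "non_monotonic": f.non_monotonic,
        })
    return pd.DataFrame(rows)
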