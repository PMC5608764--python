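"""Extraction of three-bond scalar couplings from spin-echo difference intensities.

Spin-echo difference experiments yield, per residue and coupling type, a
reference peak intensity ``I_a`` and a coupled intensity ``I_b`` related by

    I_b / I_a = cos(2 pi J tau)

where ``tau`` is the constant-time delay during which the coupling is active.
Inverting the cosine on its principal branch gives J in [0, 1/(2 tau)] Hz.
Replicated measurements are aggregated into a mean coupling with a
replicate-based uncertainty.

Two coupling types are handled, named by the nuclei involved:

``NCg``
    3J between the backbone amide nitrogen and the side-chain Cgamma;
    observed on the amide of the residue itself.
``CpCg``
    3J between the backbone carbonyl C' and Cgamma; observed on the amide
    of the *following* residue (i+1), because the carbonyl of residue i
    couples into the amide of residue i+1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

COUPLING_TYPES = ("NCg", "CpCg")

#: default constant-time delays (seconds) per coupling type
DEFAULT_TAU = {"NCg": 0.065, "CpCg": 0.050}

#: default tolerance by which |I_b/I_a| may exceed 1 before being an error
DEFAULT_CLAMP_TOL = 0.05

INPUT_COLUMNS = ["residue", "restype", "coupling_type", "replicate",
                 "I_ref", "I_coupled", "tau_s"]
OUTPUT_COLUMNS = ["residue", "coupling_type", "J_Hz", "sigma_Hz", "n", "clamped"]


@dataclass(frozen=True)
class IntensityRecord:
    """One replicate of a reference/coupled intensity pair."""

    residue: int
    coupling_type: str
    replicate: int
    I_a: float
    I_b: float
    tau: float
    restype: str = ""

    def __post_init__(self) -> None:
        if self.coupling_type not in COUPLING_TYPES:
            raise ValueError(f"unknown coupling type {self.coupling_type!r}")
        if self.I_a <= 0:
            raise ValueError("reference intensity I_a must be positive")
        if self.tau <= 0:
            raise ValueError("delay tau must be positive")


@dataclass(frozen=True)
class CouplingMeasurement:
    """Aggregated coupling constant for one residue and coupling type.

    ``sigma_J`` is the sample standard deviation over replicates (the
    spread used to weight the rotamer-population fit); ``low_confidence``
    marks single-replicate measurements whose spread is undefined.
    """

    residue: int
    coupling_type: str
    J: float
    sigma_J: float
    n_replicates: int
    clamped: bool = False
    low_confidence: bool = False


def compute_J(I_a: float, I_b: float, tau: float,
              clamp_tol: float = DEFAULT_CLAMP_TOL) -> tuple[float, bool]:
    """Invert the cosine modulation to a coupling constant in Hz.

    Returns ``(J, clamped)``. The intensity ratio is clamped to [-1, 1]
    when noise pushes it marginally outside; a ratio beyond ``1 + clamp_tol``
    in magnitude indicates mis-paired peaks and raises ``ValueError``.
    """
    if I_a <= 0:
        raise ValueError("reference intensity I_a must be positive")
    if tau <= 0:
        raise ValueError("delay tau must be positive")
    ratio = I_b / I_a
    clamped = False
    if abs(ratio) > 1.0:
        if abs(ratio) > 1.0 + clamp_tol:
            raise ValueError(
                f"|I_b/I_a| = {abs(ratio):.4f} exceeds 1 + clamp_tol "
                f"({1.0 + clamp_tol:.4f}); check peak pairing")
        ratio = float(np.clip(ratio, -1.0, 1.0))
        clamped = True
    J = float(np.arccos(ratio) / (2.0 * np.pi * tau))
    return J, clamped


def aggregate_replicates(records: list[IntensityRecord],
                         clamp_tol: float = DEFAULT_CLAMP_TOL,
                         sigma_mode: str = "sd") -> CouplingMeasurement:
    """Combine replicate intensity pairs into one coupling measurement.

    All records must belong to one residue and coupling type and share the
    same delay. ``sigma_mode`` selects "sd" (sample standard deviation,
    default) or "sem" (standard error of the mean) for the uncertainty.
    """
    if not records:
        raise ValueError("no intensity records to aggregate")
    residues = {r.residue for r in records}
    types = {r.coupling_type for r in records}
    taus = {r.tau for r in records}
    if len(residues) > 1 or len(types) > 1:
        raise ValueError("records span more than one residue/coupling type")
    if len(taus) > 1:
        raise ValueError(f"mixed tau values within one group: {sorted(taus)}")
    if sigma_mode not in ("sd", "sem"):
        raise ValueError("sigma_mode must be 'sd' or 'sem'")

    Js, clamp_flags = [], []
    for rec in records:
        J, clamped = compute_J(rec.I_a, rec.I_b, rec.tau, clamp_tol)
        Js.append(J)
        clamp_flags.append(clamped)
    n = len(Js)
    if n < 3:
        warnings.warn(
            f"residue {records[0].residue} {records[0].coupling_type}: "
            f"only {n} replicate(s); uncertainty estimate is weak",
            stacklevel=2)
    J_mean = float(np.mean(Js))
    if n == 1:
        sigma = 0.0
    else:
        sigma = float(np.std(Js, ddof=1))
        if sigma_mode == "sem":
            sigma /= np.sqrt(n)
    return CouplingMeasurement(
        residue=records[0].residue,
        coupling_type=records[0].coupling_type,
        J=J_mean,
        sigma_J=sigma,
        n_replicates=n,
        clamped=any(clamp_flags),
        low_confidence=(n == 1),
    )


def read_intensity_table(path: str | Path, amide_offset: bool = True) -> pd.DataFrame:
    """Read a TSV of replicate intensity pairs.

    Columns: residue, restype, coupling_type, replicate, I_ref, I_coupled,
    tau_s. With ``amide_offset=True`` (default) the CpCg rows are assumed to
    be recorded under the amide residue on which the signal is observed
    (i+1) and are re-attributed to the residue owning the coupling (i).
    Tables already recorded per-owner should be read with
    ``amide_offset=False``.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(INPUT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"intensity table missing columns: {sorted(missing)}")
    df = df.copy()
    if amide_offset:
        is_cp = df["coupling_type"] == "CpCg"
        df.loc[is_cp, "residue"] = df.loc[is_cp, "residue"] - 1
        # restype of a shifted row describes the amide residue, not the
        # coupling's owner; take the owner's type from its NCg rows
        type_map = (df.loc[~is_cp].groupby("residue")["restype"]
                    .agg(lambda s: s.iloc[0]))
        df.loc[is_cp, "restype"] = (
            df.loc[is_cp, "residue"].map(type_map).fillna(df.loc[is_cp, "restype"]))
    return df


def extract_couplings(df: pd.DataFrame,
                      clamp_tol: float = DEFAULT_CLAMP_TOL,
                      sigma_mode: str = "sd") -> list[CouplingMeasurement]:
    """Aggregate an intensity table (as from :func:`read_intensity_table`)."""
    out = []
    for (residue, ctype), grp in df.groupby(["residue", "coupling_type"], sort=True):
        records = [
            IntensityRecord(residue=int(residue), coupling_type=str(ctype),
                            replicate=int(row.replicate), I_a=float(row.I_ref),
                            I_b=float(row.I_coupled), tau=float(row.tau_s),
                            restype=str(row.restype))
            for row in grp.itertuples()
        ]
        out.append(aggregate_replicates(records, clamp_tol, sigma_mode))
    return out


def couplings_to_frame(measurements: list[CouplingMeasurement]) -> pd.DataFrame:
    """Tabulate measurements with the standard output schema."""
    return pd.DataFrame(
        [{"residue": m.residue, "coupling_type": m.coupling_type,
          "J_Hz": m.J, "sigma_Hz": m.sigma_J, "n": m.n_replicates,
          "clamped": m.clamped} for m in measurements],
        columns=OUTPUT_COLUMNS)
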