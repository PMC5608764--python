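"""Synthetic data generators for every analysis stage.

Each generator produces inputs with the statistical structure the
corresponding analysis assumes, from prescribed ground truth:

* spin-echo difference intensity tables from prescribed rotamer populations
  (cosine-modulated ratios with additive Gaussian intensity noise),
* CSP titration tables from prescribed Kd / dCS_max / c via the single-site
  depletion isotherm,
* multi-model PDB ensembles whose aromatic side chains are built at
  prescribed chi1 angles with ideal internal coordinates,
* per-frame atom-pair distance trajectories from simple distributions
  (constant, two-state exchange, log-normal).

All randomness flows from ``SynthSpec.seed``; a fixed seed gives
byte-identical outputs. Noise is additive Gaussian, applied independently
to each measured quantity (both intensities of a pair, each chemical-shift
axis), so ratio- and metric-level noise emerge naturally rather than being
imposed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np
import pandas as pd

from . import titration as _titration
from .jcoupling import INPUT_COLUMNS
from .rotamerfit import KarplusTable

#: ideal internal coordinates (Angstrom / degrees) for the chi1 fragment
BOND_N_CA = 1.458
BOND_CA_CB = 1.530
BOND_CB_CG = 1.510
BOND_CA_C = 1.525
BOND_C_O = 1.231
ANGLE_N_CA_CB = 110.5
ANGLE_CA_CB_CG = 113.8
ANGLE_N_CA_C = 111.0

SUPPORTED_RESIDUES = {"PHE", "TYR", "HIS", "TRP"}


@dataclass
class SynthSpec:
    """Ground truth and noise model for one synthetic data set."""

    seed: int
    n_replicates: int = 3
    noise_sd_intensity: float = 0.0  # fraction of the reference intensity
    noise_sd_shift: float = 0.0      # ppm, per chemical-shift axis
    true_values: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.noise_sd_intensity < 0 or self.noise_sd_shift < 0:
            raise ValueError("noise parameters must be non-negative")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


# ---------------------------------------------------------------------------
# scalar-coupling intensity tables


def gen_coupling_table(spec: SynthSpec, karplus: KarplusTable,
                       tau_by_type: dict[str, float],
                       reference_intensity: float = 1000.0,
                       amide_convention: bool = True) -> pd.DataFrame:
    """Simulate replicate reference/coupled intensity pairs.

    ``spec.true_values["populations"]`` maps residue number to the simplex
    triple (p_trans, p_gauche+, p_gauche-); ``spec.true_values`` may also
    carry ``"restypes"`` (residue -> name, default PHE). For each residue,
    coupling type and replicate the coupled intensity is
    ``I_a_clean * cos(2 pi J_calc tau)`` with the population-weighted
    Karplus mixture J_calc; Gaussian noise of SD
    ``noise_sd_intensity * reference_intensity`` is added independently to
    both intensities.

    With ``amide_convention=True`` (default) CpCg rows are written under the
    amide residue number (i+1) on which such signals are observed, matching
    what the default reader expects.

    Raises when ``J_calc * tau > 0.5`` for any residue/type: past that point
    the cosine leaves its invertible branch and the simulated table could
    not be analysed.
    """
    populations: dict[int, tuple] = spec.true_values["populations"]
    restypes: dict[int, str] = spec.true_values.get("restypes", {})
    rng = spec.rng()
    sd = spec.noise_sd_intensity * reference_intensity
    rows = []
    for residue in sorted(populations):
        p = np.asarray(populations[residue], dtype=float)
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"populations for residue {residue} are not on "
                             f"the simplex: {p}")
        restype = restypes.get(residue, "PHE")
        for ctype, tau in tau_by_type.items():
            if tau <= 0:
                raise ValueError("tau must be positive")
            J_calc = float(p @ karplus.row(ctype))
            if J_calc * tau > 0.5:
                raise ValueError(
                    f"residue {residue} {ctype}: J*tau = {J_calc * tau:.3f} "
                    "> 0.5 aliases the cosine; shorten tau or reduce J")
            table_residue = residue + 1 if (amide_convention
                                            and ctype == "CpCg") else residue
            for replicate in range(1, spec.n_replicates + 1):
                I_a = reference_intensity + rng.normal(0.0, sd) if sd else \
                    reference_intensity
                I_b = (reference_intensity * np.cos(2 * np.pi * J_calc * tau)
                       + (rng.normal(0.0, sd) if sd else 0.0))
                rows.append({"residue": table_residue, "restype": restype,
                             "coupling_type": ctype, "replicate": replicate,
                             "I_ref": I_a, "I_coupled": I_b, "tau_s": tau})
    return pd.DataFrame(rows, columns=INPUT_COLUMNS)


# ---------------------------------------------------------------------------
# CSP titration tables


def gen_titration(spec: SynthSpec,
                  schedule: list[tuple[float, float]],
                  hn_fraction: float = 1.0) -> pd.DataFrame:
    """Simulate a per-residue CSP titration table.

    ``spec.true_values`` carries ``"Kd"`` (molar), ``"c"`` (default 1.0) and
    ``"dCS_max"`` (residue -> ppm). ``schedule`` lists (P0, L0) in molar for
    each titration point. The combined shift follows the depletion isotherm;
    it is partitioned into the proton and nitrogen axes by ``hn_fraction``
    (1.0 = all on dHN, the default) and Gaussian noise of SD
    ``noise_sd_shift`` ppm is added to each axis independently.
    Output uses the titration TSV schema (micromolar / ppm).
    """
    Kd = float(spec.true_values["Kd"])
    c = float(spec.true_values.get("c", 1.0))
    dcs_max: dict[int, float] = spec.true_values["dCS_max"]
    if not 0.0 <= hn_fraction <= 1.0:
        raise ValueError("hn_fraction must lie in [0, 1]")
    rng = spec.rng()
    rows = []
    for residue in sorted(dcs_max):
        for point, (P0, L0) in enumerate(schedule):
            dcs = float(_titration.predict(Kd, L0, P0, c, dcs_max[residue]))
            dHN = hn_fraction * dcs
            # the nitrogen axis enters the combined metric scaled by 1/6.41,
            # so the residual share is placed there pre-scaled back up
            dN = (1.0 - hn_fraction) * dcs * _titration.NITROGEN_SCALE
            if spec.noise_sd_shift:
                dHN += rng.normal(0.0, spec.noise_sd_shift)
                dN += rng.normal(0.0, spec.noise_sd_shift)
            rows.append({"residue": residue, "point_index": point,
                         "P0_uM": P0 * 1e6, "L0_uM": L0 * 1e6,
                         "dHN_ppm": dHN, "dN_ppm": dN})
    return pd.DataFrame(rows, columns=_titration.TITRATION_COLUMNS)


# ---------------------------------------------------------------------------
# coordinate ensembles with prescribed chi1


def _place_fourth_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                       bond: float, angle_deg: float,
                       dihedral_deg: float) -> np.ndarray:
    """Natural extension (NeRF): position D with given internal coordinates.

    D is placed at distance ``bond`` from C, with angle B-C-D ``angle_deg``
    and dihedral A-B-C-D ``dihedral_deg`` under the standard sign
    convention.
    """
    theta = np.radians(angle_deg)
    phi = np.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([-bond * np.cos(theta),
                        bond * np.sin(theta) * np.cos(phi),
                        bond * np.sin(theta) * np.sin(phi)])
    frame = np.column_stack([bc, m, n])
    return c + frame @ d_local


def _build_residue(chi1_target: float) -> dict[str, np.ndarray]:
    """Ideal-geometry chi1 fragment N, CA, CB, CG (+ backbone C, O)."""
    ca = np.zeros(3)
    n = np.array([BOND_N_CA, 0.0, 0.0])
    ang = np.radians(ANGLE_N_CA_CB)
    cb = BOND_CA_CB * np.array([np.cos(ang), np.sin(ang), 0.0])
    cg = _place_fourth_atom(n, ca, cb, BOND_CB_CG, ANGLE_CA_CB_CG,
                            chi1_target)
    ang_c = np.radians(-ANGLE_N_CA_C)
    c = BOND_CA_C * np.array([np.cos(ang_c), np.sin(ang_c), 0.0])
    o = c + np.array([0.0, -BOND_C_O, 0.0])
    return {"N": n, "CA": ca, "CB": cb, "CG": cg, "C": c, "O": o}


def gen_ensemble_structure(spec: SynthSpec,
                           chi1_targets: list[dict[int, float]],
                           restypes: dict[int, str] | None = None,
                           jitter: float = 0.0):
    """Build an in-memory ensemble with prescribed chi1 angles.

    ``chi1_targets`` lists, per model, a mapping residue number -> target
    chi1 in degrees (|target| <= 180). ``restypes`` names each residue
    (default PHE; only the single-Cgamma aromatics PHE/TYR/HIS/TRP are
    supported). ``jitter`` adds Gaussian coordinate noise (Angstrom, SD)
    after ideal construction. Residues are laid out on a translated grid;
    only intra-residue geometry is meaningful.

    The returned :class:`~rrmswitch.structrot.StructureEnsemble` holds
    full-precision coordinates: the constructed dihedral matches the target
    essentially exactly. Serialising through PDB text
    (:func:`gen_ensemble`) rounds coordinates to 0.001 Angstrom, which
    perturbs recomputed chi1 by up to a few hundredths of a degree.
    """
    restypes = restypes or {}
    rng = spec.rng()
    structure = gemmi.Structure()
    structure.name = "synthetic chi1 ensemble"
    for model_idx, targets in enumerate(chi1_targets, start=1):
        model = gemmi.Model(model_idx)
        chain = gemmi.Chain("A")
        for residue_num in sorted(targets):
            target = float(targets[residue_num])
            if abs(target) > 180.0:
                raise ValueError(f"|chi1 target| > 180 for residue {residue_num}")
            resname = restypes.get(residue_num, "PHE")
            if resname not in SUPPORTED_RESIDUES:
                raise ValueError(f"unsupported residue name {resname!r}; "
                                 f"supported: {sorted(SUPPORTED_RESIDUES)}")
            atoms = _build_residue(target)
            offset = np.array([20.0 * residue_num % 1000,
                               7.0 * (residue_num % 13), 0.0])
            residue = gemmi.Residue()
            residue.name = resname
            residue.seqid = gemmi.SeqId(residue_num, " ")
            for name, pos in atoms.items():
                xyz = pos + offset
                if jitter:
                    xyz = xyz + rng.normal(0.0, jitter, size=3)
                atom = gemmi.Atom()
                atom.name = name
                atom.element = gemmi.Element(name[0])
                atom.pos = gemmi.Position(*xyz)
                atom.occ = 1.0
                residue.add_atom(atom)
            chain.add_residue(residue)
        model.add_chain(chain)
        structure.add_model(model)
    structure.setup_entities()
    from .structrot import StructureEnsemble

    return StructureEnsemble(models=list(structure), source="<synthetic>",
                             structure=structure)


def gen_ensemble(spec: SynthSpec,
                 chi1_targets: list[dict[int, float]],
                 restypes: dict[int, str] | None = None,
                 jitter: float = 0.0) -> str:
    """Multi-model PDB text with prescribed chi1 angles.

    See :func:`gen_ensemble_structure`; this serialises the same ensemble
    to standard ATOM/MODEL/ENDMDL records (coordinates rounded to the PDB
    fixed-point format).
    """
    ensemble = gen_ensemble_structure(spec, chi1_targets, restypes, jitter)
    return ensemble.structure.make_pdb_string()


# ---------------------------------------------------------------------------
# per-frame distance trajectories


def gen_distance_trajectory(spec: SynthSpec, restraint_ids: list[str],
                            frame_count: int) -> pd.DataFrame:
    """Simulate per-frame distances for a set of restraints.

    ``spec.true_values["distributions"]`` maps restraint_id to one of
    ``("constant", d)``, ``("two_state", d1, d2, p1)`` or
    ``("lognormal", mu, sigma)`` (mu/sigma on the log scale, Angstrom).
    Returns a frame table with columns (frame, restraint_id, r).
    """
    if frame_count < 1:
        raise ValueError("frame_count must be >= 1")
    dists: dict = spec.true_values["distributions"]
    rng = spec.rng()
    rows = []
    for rid in restraint_ids:
        kind, *params = dists[rid]
        if kind == "constant":
            r = np.full(frame_count, float(params[0]))
        elif kind == "two_state":
            d1, d2, p1 = float(params[0]), float(params[1]), float(params[2])
            state = rng.random(frame_count) < p1
            r = np.where(state, d1, d2)
        elif kind == "lognormal":
            r = rng.lognormal(float(params[0]), float(params[1]), frame_count)
        else:
            raise ValueError(f"unknown distance distribution {kind!r}")
        if np.any(r <= 0):
            raise ValueError(f"non-positive distance generated for {rid}")
        for frame in range(frame_count):
            rows.append({"frame": frame, "restraint_id": rid,
                         "r": float(r[frame])})
    return pd.DataFrame(rows, columns=["frame", "restraint_id", "r"])
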