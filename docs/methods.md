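# Methods

This note records the models implemented in `rrmswitch`, their
assumptions, the defaults that matter, and what the synthetic-data tests
do and do not demonstrate about real data.

## Scalar couplings from spin-echo difference intensities

The coupling evolution during the constant-time delay τ modulates the
coupled-experiment peak intensity as *I*ᵦ/*I*ₐ = cos(2πJτ). We invert on
the principal branch, so J ∈ [0, 1/(2τ)] Hz; for the delays used here
(τ = 65 ms for ³J NCᵞ, 40–50 ms for ³J C′Cᵞ, both overridable per table)
that window comfortably contains the 0–4 Hz range of aromatic
side-chain couplings. Noise can push |*I*ᵦ/*I*ₐ| marginally past 1 when J
is near zero; ratios within `clamp_tol` (default 0.05) of the valid range
are clamped and flagged, anything beyond is treated as a peak-pairing
error. Replicates (≥3 recommended; fewer triggers a warning) are averaged
and σ_J is their sample SD — SEM is available via `sigma_mode="sem"` for
labs that prefer it; the SD choice is deliberate because the χ² weights
downstream expect a per-measurement spread, not a mean-precision.

Attribution: a ³J C′Cᵞ coupling of residue *i* is read off the amide of
residue *i*+1. Because recording conventions differ between labs, the
table reader takes `amide_offset` (default true: tables carry the observed
amide's number and the reader shifts C′Cᵞ rows back to the owner residue).
The synthetic generator writes tables in the amide convention so the
default pipeline round-trips.

## Three-site rotamer population fit

Assumption: the side chain exchanges rapidly among the three staggered
χ1 states, so each measured coupling is the population-weighted average of
per-state Karplus expectations. The rotamer labels follow the convention
standard for this analysis: gauche+ at χ1 = −60°, gauche− at +60°, trans
at 180° (`relabel_iupac` emits the opposite labelling for
interoperability).

The χ² objective is quadratic in the populations, minimised over the
probability simplex in two free coordinates (SLSQP with bound constraints
and the linear inequality), multi-started from the three vertices and the
barycentre because the constrained minimum can sit on the boundary.
σ values are floored at 0.05 Hz so that degenerate replicate agreement
cannot produce infinite weights. A dense simplex grid search
(`grid_fit`, 0.5% resolution) is kept as the assumption-free reference;
the optimiser is required to agree with it to 0.01 per population.

Identifiability: with both coupling types the 2×3 Karplus matrix plus the
normalisation row is generically rank 3 and the fit is unique — the rank
is checked, not assumed. With a single coupling type the solution set is a
segment on the simplex; the fit is flagged `underdetermined` and the
per-population min/max over that segment is computed by linear
programming and reported alongside the point estimate. Both coupling
types are fitted jointly by default (a per-type separate fit is available)
since the joint fit is what makes the problem well-posed.

Karplus constants are required configuration. The packaged default file
carries representative literature three-site values for aromatic residues
(NCᵞ: 2.35/0.45/0.45 Hz; C′Cᵞ: 0.60/3.95/0.60 Hz for trans/g+/g−);
laboratories calibrate their own parametrisations and should override the
file. The test suite deliberately uses self-consistent synthetic constants
so that no conclusion rests on any particular published parametrisation.

## Structure-based χ1 analysis and UP/DOWN calls

χ1 is the signed N–Cα–Cβ–Cγ dihedral (standard convention, range
(−180°, 180°]); the fourth atom is Cγ, the single gamma carbon of
Phe/Tyr/His/Trp — other residue classes are out of scope. Angles are
binned to the nearest staggered centre under circular distance; an exact
tie (60° from two centres) is broken toward trans and flagged.

The binding surface is called UP or DOWN per conformer by comparing the
rotamers of six interface aromatics against the two joint signatures
(UP: 426 g+, 428 g+, 429 g+, 455 g+, 466 t, 468 t; DOWN: 426 t, 428 t,
429 g+, 455 t, 466 g−, 468 g+, in construct numbering). A call requires
an exact match of all six; anything else is MIXED rather than
nearest-template, because the states are defined as exact signatures and a
partial match is biologically a distinct (transition or artefactual)
configuration. Deposited coordinates often use their own numbering; the
offset is auto-detected by matching the six template residue types, or
set explicitly.

Ensemble RMSD-to-mean uses the iterative scheme standard for NMR bundles:
superpose every model on the current mean by unweighted least-squares
rotation/translation (Kabsch, via `scipy.spatial.transform`), recompute
the mean, repeat until the mean moves less than 10⁻⁶ Å RMS. Selections
are residue ranges crossed with "backbone" (N, Cα, C′, O) or "heavy"
(all non-hydrogen) atom classes; hydrogens are always excluded from
"heavy", matching the usual convention for such statistics.

## CSP affinity fitting

The combined shift uses the conventional nitrogen scaling of 6.41. The
isotherm is the exact single-site mass-balance solution, valid when peak
positions are fast-exchange population averages; intermediate exchange is
not modelled, and series that are non-monotonic in ligand beyond 3× the
noise floor are flagged. The correction coefficient *c* (absorbing
protein-quantification error) defaults to 1.0 and is only fitted on
request (bounds [0.5, 2]), because freeing it on clean data merely
inflates the Kd uncertainty.

Per-residue fits are averaged (unweighted mean ± sample SD) over
resonances passing the acceptance rule — ΔCSₘₐₓ ≥ 0.03 ppm and relative
Kd standard error ≤ 100% — mirroring how per-resonance Kds are combined
in titration practice; a single global fit across residues is possible
but deliberately not the default, since the per-residue spread is itself
the honest uncertainty estimate. Standard errors are asymptotic
(from the fit covariance). Bounds: Kd ∈ (0, 1 M], ΔCSₘₐₓ ∈ (0, 10 ppm].

`fraction_bound` evaluates the same quadratic with c = 1 to give the
fraction of protein in complex — e.g. 96% at Kd = 66 µM, 0.8 mM protein
and a 3-fold ligand excess. Saturation at a fixed ratio rises with
concentration (≈95% at 0.6 mM protein, ≈98% at 2 mM), so the quoted
figure corresponds to the nominal mid-range concentration.

## NOE r⁻⁶ ensemble validation

The effective NOE distance over an ensemble is (⟨r⁻⁶⟩)^(−1/6), averaged
over frames/conformers and, for degenerate proton groups, over the
equivalent pairs with the same rule. Pseudo-atom selectors (QB, QD1, QQG,
…) are expanded to the protons actually present in the model by prefix
matching; expansion was preferred over additive bound corrections because
it is the more conservative treatment and keeps the averaging rule
uniform (the restraint object still carries a correction field for
workflows that need it). Violations are max(0, r_eff − bound − tolerance)
with tolerance defaulting to 0 (report raw), binned in the conventional
0.1–0.2 / 0.2–0.3 / 0.3–0.4 / >0.4 Å bands. Distances may come from PDB
ensembles directly or from a pre-extracted (frame, restraint_id, r) TSV,
so any trajectory toolkit can feed the check without a hard dependency.

## Synthetic-data generators

The generators emulate exactly the statistical structure the estimators
assume: cosine-modulated intensity ratios with additive Gaussian noise
applied independently to both intensities of a pair (ratio noise then
emerges naturally); depletion-isotherm CSP curves with independent
Gaussian noise per shift axis; ideal-geometry χ1 fragments (standard
amino-acid bond lengths/angles, only χ1 varied, NeRF placement of Cγ)
with optional coordinate jitter; and constant / two-state / log-normal
distance trajectories. Defaults follow the measurement practice the
package targets: 3 replicates per coupling, τ = 65/50 ms, protein
0.1 mM with ligand ratios 0–4 in titrations, noise levels of order 1%
intensity and a few thousandths of a ppm.

What passing tests therefore show: the estimators are unbiased and
precise when their model holds, the optimiser finds the constrained
optimum, and the pipeline round-trips its own file formats. What they do
not show: robustness to lineshape distortion, exchange broadening,
peak-picking errors, incomplete assignments, or force-field artefacts —
none of which the generators simulate. The in-memory ensemble builder is
exact to ~10⁻¹² degrees in χ1; serialising through PDB text rounds
coordinates to 0.001 Å, which perturbs recomputed χ1 by a few hundredths
of a degree — far inside the 60°-wide rotamer bins but relevant when
asserting tight numeric identities.

## Problem sizes and numerical choices

The test suite runs at desk scale: 20–100 residues per synthetic coupling
table, 200 random cases for the optimiser-vs-grid comparison, 50 noise
seeds for Kd recovery, 10³–10⁴ frames for occupancy and r⁻⁶ statistics,
20-model bundles for RMSD — sizes chosen to pin each statistical claim
with comfortable margin while keeping the whole suite around ten seconds.
Optimiser tolerances: SLSQP ftol 10⁻¹⁴; RMSD convergence 10⁻⁶ Å; grid
oracle 0.5% simplex resolution. Degenerate inputs (empty measurement
sets, flat titration series, missing χ1 atoms, unknown pseudo-atoms,
mixed delays in a replicate group) raise or flag explicitly rather than
propagating silently.

## Known limitations

- Only χ1 of single-Cγ aromatics is analysed; χ2 and ring flips are out
  of scope, as are continuous χ1 distributions beyond the three-site
  model.
- The UP/DOWN templates are domain-specific configuration; applying them
  to another RRM requires editing the template and residue-type tables.
- The titration module assumes fast exchange and 1:1 stoichiometry;
  multi-site or cooperative binding is not modelled.
- Deposited-ensemble statistics (e.g. RMSD of a published 20-conformer
  bundle) require the public coordinates; the package computes them when
  given the files but ships no structural data.
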