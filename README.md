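# rrmswitch

Aromatic side chains exposed on the β-sheet of an RNA recognition motif
(RRM) can flip between staggered χ1 rotamers, switching the binding surface
between a low-affinity "UP" state and a high-affinity "DOWN" state and
thereby tuning which RNA sequences the domain binds tightly. `rrmswitch`
implements, as a reusable and tested Python library, the quantitative
analyses by which such a conformational switch is characterised from NMR
and structural data:

- **Scalar-coupling extraction** (`rrmswitch.jcoupling`): spin-echo
  difference experiments give intensity pairs obeying
  *I*ᵦ/*I*ₐ = cos(2π *J* τ); inverting on the principal branch yields
  ³J NCᵞ and ³J C′Cᵞ couplings with replicate-based uncertainties.
- **χ1 rotamer populations** (`rrmswitch.rotamerfit`): under a three-site
  jump model the couplings average linearly over the staggered states,
  ³J꜀ₐₗ꜀ = p₁₈₀ Jₜ + p₋₆₀ J₉₊ + p₊₆₀ J₉₋ with p₁₈₀+p₋₆₀+p₊₆₀ = 1;
  populations are fitted on the simplex by minimising
  χ² = Σ ((J꜀ₐₗ꜀ − Jₑₓₚ)/σ_Jexp)², with identifiability diagnosed and
  solution intervals reported when only one coupling type is available.
- **Structure-state classification** (`rrmswitch.structrot`): χ1
  (N–Cα–Cβ–Cγ) from multi-model PDB ensembles, nearest-staggered-rotamer
  binning, UP/DOWN surface calls from the joint signature of six interface
  aromatics, and ensemble RMSD-to-mean statistics by iterative Kabsch
  superposition.
- **Affinity from chemical shift perturbation** (`rrmswitch.titration`):
  combined shifts ΔCS = √(δHN² + (δN/6.41)²) fitted with the single-site
  depletion isotherm
  ΔCS = ΔCSₘₐₓ ((K_d+L₀+cP₀) − √((K_d+L₀+cP₀)² − 4L₀cP₀)) / (2cP₀),
  per-residue K_d averaging, and saturation-fraction arithmetic.
- **NOE ensemble validation** (`rrmswitch.ensnoe`): CYANA-style `.upl`
  restraints checked against conformer bundles or trajectory distance
  tables via the r⁻⁶ ensemble average (⟨r⁻⁶⟩)^(−1/6), with violations
  binned in the conventional 0.1 Å bands.
- **Synthetic data** (`rrmswitch.synth`): seeded generators for all of the
  above with prescribed ground truth, so every estimator is exercised
  against known answers without any external data.

## Worked example

```python
from rrmswitch import titration

frac = titration.fraction_bound(Kd=66e-6, P0=8e-4, L0=2.4e-3)
print(f"{frac * 100:.0f}% of the protein is in the complex")
```

prints `96% of the protein is in the complex`: with a 66 µM dissociation
constant, 0.8 mM protein and a 3-fold RNA excess, essentially all of the
protein NMR signal arises from the bound state — the arithmetic behind
choosing a 1:3 ratio for structure determination of a weak complex.

The scripts in `examples/` each exercise one capability end to end.
`examples/02_kd_titration.py` simulates a six-residue titration at
Kd = 66 µM with 0.003 ppm shift noise and refits it:

```
average Kd = 71 +/- 6 uM from 6 resonances
```

and `examples/03_state_classification.py` builds UP- and DOWN-posed
conformer bundles and classifies every model:

```
UP-state bundle: UP 100%  DOWN 0%  MIXED 0%  (10 models)
DOWN-state bundle: UP 0%  DOWN 100%  MIXED 0%  (10 models)
```

A thin CLI (`rrmswitch simulate | extract-j | fit-rotamers | classify |
rmsd | fit-kd | noe-check | report`) wraps the same functions for shell
pipelines; every artifact it writes embeds the tool version, config hash
and seed.

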