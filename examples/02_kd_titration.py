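"""Fit a dissociation constant from a simulated CSP titration.

Simulates 1H-15N peak movements for six residues titrated with RNA
(Kd = 66 uM, protein at 100 uM), fits the single-site depletion isotherm
per residue, and averages the accepted Kds. Also prints the saturation
arithmetic used when choosing a protein:RNA ratio for structural work.
"""

from rrmswitch import synth, titration

schedule = [(1e-4, ratio * 1e-4)
            for ratio in (0, 0.25, 0.5, 0.75, 1, 1.5, 2, 3, 4)]
spec = synth.SynthSpec(
    seed=2, noise_sd_shift=0.003,
    true_values={"Kd": 66e-6,
                 "dCS_max": {r: 0.08 + 0.04 * i
                             for i, r in enumerate((426, 428, 429, 455,
                                                    466, 468))}})
table = synth.gen_titration(spec, schedule)

result = titration.fit_table(table)
print(f"average Kd = {result.average_Kd * 1e6:.0f} +/- "
      f"{result.sd_Kd * 1e6:.0f} uM from {result.n_resonances} resonances")
print(titration.binding_fit_frame(result).to_string(index=False))

saturation = titration.fraction_bound(Kd=66e-6, P0=8e-4, L0=2.4e-3)
print(f"\nAt 0.8 mM protein with a 1:3 protein:RNA ratio, "
      f"{saturation * 100:.0f}% of the protein is in the complex.")

# The average is an unweighted mean over residues whose peaks shift enough
# to be informative; the saturation line shows why a 3-fold RNA excess is
# enough to record NOEs on an essentially fully bound protein despite the
# modest (66 uM) affinity.
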