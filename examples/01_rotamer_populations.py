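"""Recover chi1 rotamer populations from simulated scalar couplings.

Simulates spin-echo difference intensity tables for five aromatic residues
with known rotamer populations, extracts 3J NCgamma / 3J C'Cgamma couplings
from the intensity ratios, and fits the three-site Karplus mixture back.
"""

import io

import numpy as np

from rrmswitch import jcoupling, rotamerfit, synth

karplus = rotamerfit.default_karplus()

rng = np.random.default_rng(0)
truth = {420 + i: tuple(rng.dirichlet(np.ones(3))) for i in range(5)}

spec = synth.SynthSpec(seed=1, n_replicates=3, noise_sd_intensity=0.01,
                       true_values={"populations": truth})
table = synth.gen_coupling_table(spec, karplus, jcoupling.DEFAULT_TAU)

df = jcoupling.read_intensity_table(
    io.StringIO(table.to_csv(sep="\t", index=False)))
measurements = jcoupling.extract_couplings(df)
fits = rotamerfit.fit_table(measurements, karplus).set_index("residue")

print("residue   true (t, g+, g-)        fitted (t, g+, g-)      major")
for residue, p_true in sorted(truth.items()):
    row = fits.loc[residue]
    print(f"{residue:7d}   ({p_true[0]:.2f}, {p_true[1]:.2f}, "
          f"{p_true[2]:.2f})      ({row.p_trans:.2f}, {row.p_gplus:.2f}, "
          f"{row.p_gminus:.2f})      {row.major}")

# Each triple is the fraction of time the side chain spends in the trans
# (chi1 = 180), gauche+ (-60) and gauche- (+60) staggered states; at 1%
# intensity noise the fitted populations track the truth to a few percent.
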