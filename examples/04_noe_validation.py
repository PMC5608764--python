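"""Check NOE upper-bound restraints against a simulated distance trajectory.

Simulates per-frame distances for ten restraints, three of which hop
between a satisfied and a violating distance, and reports the r^-6
ensemble-averaged effective distances against their bounds.
"""

import numpy as np

from rrmswitch import ensnoe, synth
from rrmswitch.ensnoe import AtomSelector, NOERestraint

restraints = [NOERestraint(a=AtomSelector(420 + i, "PHE", "CG"),
                           b=AtomSelector(430 + i, "TYR", "CG"),
                           upper_bound=4.0, restraint_id=f"r{i}")
              for i in range(10)]

distributions = {}
for i in range(10):
    if i in (1, 4, 8):  # these sit past their bound most of the time
        distributions[f"r{i}"] = ("two_state", 4.3, 3.9, 0.9)
    else:
        distributions[f"r{i}"] = ("lognormal", np.log(3.4), 0.05)

spec = synth.SynthSpec(seed=4, true_values={"distributions": distributions})
frames = synth.gen_distance_trajectory(spec, [f"r{i}" for i in range(10)],
                                       frame_count=500)
series = {rid: grp.sort_values("frame")["r"].to_numpy()
          for rid, grp in frames.groupby("restraint_id")}

report = ensnoe.evaluate(restraints, distances=series)
print(report.to_frame().to_string(index=False,
                                  float_format=lambda v: f"{v:.2f}"))
print(f"\nviolated: {report.n_violated}/10, "
      f"max violation {report.max_violation:.2f} A")
print(f"violation bins (A): {report.bin_counts}")

# The effective distance (mean r^-6)^(-1/6) is dominated by close
# approaches, so a restraint violates only when the ensemble spends most
# of its time beyond the bound - brief excursions are forgiven, which is
# exactly the averaging NOE intensities perform physically.
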