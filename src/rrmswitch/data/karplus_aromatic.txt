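# Default three-site Karplus expectation values (Hz) for aromatic side
# chains, one line per coupling type:
#   <type> <J_trans> <J_gauche+> <J_gauche->
# where trans/gauche+/gauche- are the staggered chi1 states at 180/-60/+60
# degrees. These are representative literature values for 3J(N-Cgamma) and
# 3J(C'-Cgamma) three-site analyses of aromatic residues; laboratories
# calibrate their own parametrization, so treat this file as a documented
# starting point and override it with your preferred constants.
NCg 2.35 0.45 0.45
CpCg 0.60 3.95 0.60
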