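# Escherichia coli K-12 W3110: Monod/yield kinetics estimated from
# mono-culture mini-bioreactor fermentations on minimal glucose medium.
# q_max is the printed specific consumption rate (negative = consumption);
# the loader stores its magnitude.  Enzyme-dynamics constants follow
# published cybernetic models (see docs/methods.md); the fermentative
# acetate yield saturates the carbon mass bound Yx + sum(Yp) = 1 and is
# overridable.
name: ecoli_k12
description: E. coli K-12 W3110, glucose fermentative/oxidative uptake plus acetate re-assimilation
metabolites: [GLU, ACE, ETH]
enzyme_defaults:
  eps_c: 0.01
  eps_i: 1.0
  delta: 0.05
pathways:
  - id: glu_ferm
    substrate: GLU
    mu_max: 0.437
    Ks: 0.112
    q_max: -2.640
    Yx: 0.165
    Yp: {ACE: 0.835}
  - id: ace
    substrate: ACE
    mu_max: 0.077
    Ks: 0.108
    q_max: -0.630
    Yx: 0.122
  - id: glu_ox
    substrate: GLU
    mu_max: 0.234
    Ks: 1.000
    q_max: -1.745
    Yx: 0.134
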