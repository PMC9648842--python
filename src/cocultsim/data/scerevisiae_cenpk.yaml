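# Saccharomyces cerevisiae CEN-PK 117D: Monod/yield kinetics estimated
# from mono-culture mini-bioreactor fermentations on minimal glucose
# medium.  The respiro-fermentative glucose pathway overflows to ethanol
# and (minor) acetate; the remainder 1 - Yx is split ETH:ACE = 9:1 by
# default and is overridable.  q_max printed as negative consumption.
name: scerevisiae_cenpk
description: S. cerevisiae CEN-PK 117D, glucose fermentative/oxidative uptake plus acetate and ethanol re-assimilation
metabolites: [GLU, ACE, ETH]
enzyme_defaults:
  eps_c: 0.01
  eps_i: 1.0
  delta: 0.05
pathways:
  - id: glu_ferm
    substrate: GLU
    mu_max: 0.299
    Ks: 0.082
    q_max: -1.648
    Yx: 0.182
    Yp: {ETH: 0.7362, ACE: 0.0818}
  - id: ace
    substrate: ACE
    mu_max: 0.017
    Ks: 0.007
    q_max: -0.058
    Yx: 0.285
  - id: eth
    substrate: ETH
    mu_max: 0.080
    Ks: 0.055
    q_max: -0.276
    Yx: 0.287
  - id: glu_ox
    substrate: GLU
    mu_max: 0.221
    Ks: 1.469
    q_max: -3.175
    Yx: 0.070
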