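# cocultsim

Cybernetic Monod-type kinetic simulation of microbial co-cultures in
batch, chemostat and glucose-pulsed continuous bioreactors.

## The problem

A fast-growing bacterium (*Escherichia coli*) competitively excludes a
slower yeast (*Saccharomyces cerevisiae*) in a glucose-fed chemostat.
Both organisms, however, overflow part of their glycolytic flux to
byproducts — acetate (ACE) for *E. coli*, ethanol (ETH) and acetate for
the yeast — and can re-assimilate those byproducts once glucose (GLU)
runs out (the diauxic shift). Square-wave pulsing of the feed
periodically starves the culture of glucose, and each famine hands the
metabolically more flexible yeast a transient fitness advantage that can
stabilise the co-culture. `cocultsim` simulates this mechanism and scans
feeding programs for coexistence.

## The model

Each species is a set of substrate-assimilation pathways with Monod
uptake gated by a virtual "key enzyme" Ψ carried in relative units:

- uptake through pathway i:  r_i = ν_i · q_max,i · Ψ_rel,i · S/(K_s,i + S) · X
- growth return:             μ_i = Y_x,i · q_max,i · Ψ_rel,i · S/(K_s,i + S)
- stoichiometry:             d[X, GLU, ACE, ETH]/dt = ψ · r, where each
  column of ψ holds +Y_x (biomass), −1 (own substrate), +Y_p (byproducts)
- enzyme dynamics:           dΨ_rel,i/dt = [ε_c + υ_i ε_i S/(K'_i+S)]/Ψ_max,i
  − (δ_i + μ) Ψ_rel,i, with Ψ_max,i = (ε_c + ε_i)/(δ_i + μ_max,i)

Resource allocation follows the matching law: the synthesis weight
υ_i = μ_i/Σμ_j distributes inducible enzyme synthesis across pathways,
and the activity weight ν_i = μ_i/max(μ) gates uptake, so the cell
dynamically commits to whichever pathway currently returns the most
growth. Species are coupled only through the shared metabolite pool of a
constant-volume reactor; in pulsed operation the dilution rate is a
square wave D(t) = D_on while (t mod 1/w) < s/w and 0 otherwise.

Packaged parameter files carry the Monod/yield constants of
*E. coli* K-12 W3110 (glucose fermentative/oxidative + acetate uptake)
and *S. cerevisiae* CEN-PK 117D (those plus ethanol uptake), estimated
from mono-culture mini-bioreactor fermentations.

## Worked example

```python
import numpy as np
import cocultsim as cs

ecoli = cs.load_species("ecoli_k12")
yeast = cs.load_species("scerevisiae_cenpk")

# constant dilution: competitive exclusion of the yeast
chem = cs.run_chemostat([ecoli, yeast], D=0.1, t_end=80)
f = cs.biomass_fractions(chem)
print(f"yeast share at 80 h (chemostat): {f['frac_scerevisiae_cenpk'].iloc[-1]:.3f}")

# low-frequency glucose pulsing (2 h feed-on : 5 h feed-off at D_on = 0.1/h)
fp = cs.FeedProgram(mode="pulsed", D_on=0.1, w=0.14, s=0.28)
puls = cs.run_pulsed([ecoli, yeast], fp, t_end=80)
fy = cs.biomass_fractions(puls)["frac_scerevisiae_cenpk"]
print(f"yeast share at 80 h (pulsed):    {fy.iloc[-1]:.3f}")
```

prints

```
yeast share at 80 h (chemostat): 0.057
yeast share at 80 h (pulsed):    0.152
```

i.e. after 80 h of constant feeding the yeast is down to ~6% of the
biomass and still declining, while under 2h:5h glucose pulsing it holds
~15%: each feed-off famine exhausts glucose, the yeast re-induces its
ethanol-uptake enzyme, and the diauxic growth pulse offsets its
disadvantage during the glucose phase.

The same machinery is exposed on the command line
(`cocultsim simulate-batch|simulate-chemostat|simulate-pulse|scan|fit|generate-data`,
each driven by a YAML config), and `cocultsim.coexistence_scan` sweeps a
(D, w, s) grid and reports per-point persistence plus the largest
dilution rate that still supports coexistence.

A calibration workflow is included: `generate_batch_dataset` emulates
the mini-bioreactor mono-culture design (initial glucose ladder
20…1.25 g/L, 3-h sampling, multiplicative noise) and
`KineticsModel(...).fit()` recovers Monod/yield parameters from such
data with confidence intervals and a `summary()` table.

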