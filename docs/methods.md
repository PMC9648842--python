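# Methods

## Model

`cocultsim` implements a cybernetic extension of Monod kinetics for
multi-pathway, multi-species growth. A species σ carries ω pathways,
each consuming one substrate from the shared pool M = (GLU, ACE, ETH).
Pathway uptake is

    r_i = ν_i · q_max,i · Ψ_rel,i · H_i · X,      H_i = S_i/(K_s,i + S_i)

with X the species biomass (g/L) and Ψ_rel,i ∈ [0, 1] the relative level
of a lumped virtual "key enzyme" gating the pathway. The stoichiometric
matrix ψ (rows = biomass + metabolites, one column per pathway; +Y_x in
the biomass row, −1 in the own-substrate row, +Y_p in byproduct rows)
converts the uptake vector into concentration rates, so the per-species
contribution to the reactor is ψ·r. Byproduct formation is therefore
yield-coupled to uptake, not modelled as a separate secretion flux.

Enzyme levels follow, in relative (per-biomass, intensive) form,

    dΨ_rel,i/dt = [ε_c,i + υ_i · ε_i,i · S_i/(K'_i + S_i)] / Ψ_max,i
                  − (δ_i + μ) · Ψ_rel,i,
    Ψ_max,i = (ε_c,i + ε_i,i)/(δ_i + μ_max,i),

where μ is the species' realized total growth rate (dilution of the
enzyme pool by growth). The normalisation Ψ_max is chosen so that
Ψ_rel = 1 is the exact fixed point under full allocation, saturating
substrate and growth at μ_max — and makes q_max the uptake rate of a
fully committed cell. Ψ_rel ≤ 1 then holds along any trajectory
provided the resting constitutive level does not exceed that fixed
point, i.e. ε_c·μ_max ≤ δ·ε_i, and induction does not saturate below
growth saturation, K' ≥ K_s (a slowly degrading, non-growing cell would
otherwise accumulate more enzyme than a fully growing one). The
packaged defaults satisfy both with wide margin; a property test
exercises random parameter draws over this admissible domain.

Allocation is the matching law against the growth objective. The
un-gated pathway returns μ_i = Y_x,i·q_max,i·Ψ_rel,i·H_i are compared;
υ_i = μ_i/Σ_j μ_j multiplies inducible enzyme synthesis and
ν_i = μ_i/max_j μ_j gates uptake. The returns deliberately exclude ν
itself (no circularity: the law compares potential returns) but include
the current enzyme level, the convention of the classical cybernetic
literature. When every return is numerically zero (Σμ ≤ 1e-12) υ is
uniform and ν ≡ 1; this is harmless because uptake is already nulled by
H, while constitutive synthesis ε_c keeps a basal enzyme level from
which a pathway can re-induce. The realized growth rate is Σ_i ν_i μ_i,
so simultaneous consumption of several substrates contributes additively
— a species in a mixed-substrate famine can transiently grow faster than
any single pathway's μ_max·H.

Species interact only through the well-mixed pool of a constant-volume
reactor: dX_k/dt = (Σν_iμ_i)_k X_k − D(t) X_k and
dM/dt = D(t)(feed − M) + Σ_k (ψ·r)_k rows. The joint right-hand side
sums species contributions simultaneously; a randomized per-step species
ordering would coincide with this in the small-step limit but is not
reproducible, so the deterministic joint form is used. In pulsed
operation D(t) is a square wave: D_on while (t mod 1/w) < s/w, else 0
(time average s·D_on). The rate named in an on:off schedule is read as
the on-phase rate; `FeedProgram(D_is_average=True)` reinterprets it as
the average.

## Numerics

The joint ODE system is integrated with `scipy.solve_ivp` (LSODA,
rtol 1e-7, atol 1e-9 by default; 1e-6/1e-8 for scans) restarted at every
pulse edge, so discontinuities in D(t) are never stepped across — the
wave is exactly piecewise constant within each solver segment and
results are reproducible across solver choices. Output is sampled on a
uniform reporting grid (0.05 h default, 0.1 h in scans); concentrations
are clamped to zero below 1e-12 g/L at segment boundaries; cybernetic
diagnostics (μ_i, υ, ν, realized μ) are recomputed from the reported
states so they are always consistent with them. Halving the tolerances
moves a 30-h batch endpoint by < 1e-4 relative (tested).

A `fixed_enzymes` species mode pins Ψ_rel ≡ 1, reducing the framework to
classical Monod kinetics. This baseline is used wherever textbook closed
forms are the oracle (batch Monod trajectories, the chemostat steady
state S* = K_s·D/(μ_max − D), X* = Y_x(S_feed − S*)); note the full
cybernetic system settles at a slightly different steady state because
the enzyme level at μ = D < μ_max is below 1, shifting the residual
substrate upward. The closed forms are exact only when μ_max equals
Y_x·q_max exactly, so oracle species are constructed that way.

## Parameters

Packaged kinetics (h⁻¹, g/L, g/g): per species and pathway, μ_max, K_s,
q_max (stored as a positive magnitude; parameter files carry the
conventional negative consumption sign and the loader takes |q|), and
Y_x. Growth and uptake are linked by μ_max = Y_x·q_max; the loader
enforces agreement within 2% or the printed 3-decimal precision
(whichever is looser — one yeast acetate row is consistent only at
printed precision: 0.285 × 0.058 = 0.01653 ≈ 0.017).

Constants that are not published for these strains and are set as
package defaults (all overridable per pathway in the species files):

- ε_c/ε_i = 0.01 (constitutive share of enzyme synthesis); only the
  ratio matters in relative form, so ε_i = 1 enzyme-unit/h.
- δ = 0.05 h⁻¹ enzyme degradation, a typical turnover scale in
  cybernetic growth models.
- K' = K_s (induction saturates where uptake does).
- Byproduct yields: fermentative pathways saturate the carbon mass
  bound, Y_p = 1 − Y_x (E. coli glucose fermentation → ACE; yeast
  glucose fermentation → ETH:ACE split 9:1); oxidative and
  re-assimilation pathways produce no byproducts. The bound
  Y_x + ΣY_p ≤ 1 is validated on load, the remainder being CO₂ and
  maintenance.
- Initial enzyme state: the resting-cell constitutive steady state
  Ψ_rel(0) = (ε_c/δ)/Ψ_max (≈ 0.1 at the defaults), configurable per
  scenario.

Quantities that depend mainly on the published Monod/yield constants
(steady states, washout thresholds, pulse geometry, diauxic ordering)
are insensitive to these choices; quantities set by induction kinetics —
the peak growth rate reached before glucose exhaustion in small-glucose
batches, the depth of famine-phase re-induction, and through it the
high-D exclusion rate in the coexistence scan — shift by several
percentage points across plausible enzyme-constant choices. The batch
growth-rate-reduction statistic, for instance, ranges from ~8% (for a
glucose-pre-adapted inoculum) to ~18.5% (resting inoculum, packaged
defaults) between defensible settings. The packaged defaults are fixed
once, not fitted.

Extended uptake laws (product or competitive inhibition) are a
documented extension point (`monod_fraction` is the single shipped
form).

## Scenarios and metrics

Batch mono-cultures start at 0.05 g/L biomass (≈ 0.1 OD at an assumed
0.5 gDW/L per OD unit) in 20…1.25 g/L glucose. Co-culture runs start
1:1 by mass at 0.1 g/L total in 20 g/L glucose, run 10 h in batch, then
switch to the feed (30 g/L GLU) — mirroring the cultivation protocol.
The growth-rate-reduction statistic takes the maximum of the realized μ
over the reporting grid after a 0.5 h burn-in (skipping the
enzyme-initialization transient).

Species fractions are biomass-concentration fractions, the model's
state variable. Flow-cytometry event fractions are not comparable
without a cells-per-gram conversion (per-cell mass differs ~50× between
the yeast and the bacterium and no conversion is published), so
comparisons to measured event fractions are qualitative only.

Coexistence scans integrate 200 h per (D, w, s) point (≥ 20 pulse
periods on the default grids, D ∈ {0.025…0.3}, w, s ∈ {0.1…0.5}),
average each species' fraction over the final 20% of the run, and call
a species persistent above a 1% fraction threshold. This is a
finite-horizon proxy: slow competitive exclusion (rates of order
0.005 h⁻¹ arise at high D under the default byproduct yields, because
both species ride out famines on byproducts at similar maximal rates —
yeast on ethanol at 0.080 h⁻¹, the bacterium on acetate at 0.077 h⁻¹)
is classified as coexistence whenever the excluded fraction has not yet
crossed the threshold. The per-point trajectory and the minimum
fraction over the window are retained so users can tighten the verdict.
Scan points that fail to integrate are recorded with an error status
without aborting the scan, and interrupted scans resume from the
already-written rows.

## Synthetic data and fitting

`generate_batch_dataset` emulates the mini-bioreactor design: one batch
simulation per initial-glucose condition (default ladder 20, 10, 5,
2.5, 1.25 g/L), destructive sampling every 3 h to 30 h (36 h for
ethanol-capable species), channels X/GLU/ACE/ETH. Noise is
multiplicative Gaussian, obs = true·(1 + cv·z), clamped at zero —
matching the ~400-fold dynamic range of the measurements — with an
optional additive floor (default off; 0.01 g/L mimics an HPLC detection
limit). Replicate wells are independent noise draws around the shared
true trajectory. Regeneration from (design, seed) is bit-identical. The
generator does not emulate well-to-well biological variation, sampling
dead volume, evaporation, or cross-channel error correlation, so
passing recovery tests demonstrate estimator correctness under the
stated error model, not robustness to real instrument artefacts.

`KineticsModel` fits Monod/yield parameters (μ_max, K_s, q_max, Y_x
only — enzyme constants are never fitted) by bounded trust-region least
squares over all observed channels jointly, weighted 1/RMS per channel
so g/L-scale glucose and sub-g/L byproducts carry comparable influence.
Wherever q_max is not itself free it is tied to μ_max/Y_x, keeping the
growth/uptake consistency exact along the search path; a free q_max is
instead steered by a penalty residual keeping |μ_max − Y_x·q_max|
within 2% of μ_max. When Y_x changes on a pathway with byproducts, the
byproduct yields rescale by (1 − Y_x)/(1 − Y_x,old), preserving the
byproduct split of non-biomass carbon. Standard errors come from the
Gauss-Newton quadratic approximation at the optimum; K_s is weakly
identified under 3-h sampling (glucose crosses the K_s region between
samples), and its recovery error is accordingly an order of magnitude
larger than for μ_max and Y_x.

## Design notes

- The printed enzyme-balance equation can be read with biomass X inside
  the inducible synthesis term; since Ψ_rel ∈ [0,1] is only well-defined
  for an intensive quantity, the default omits X there, and
  `enzyme_synthesis_scaled_by_biomass` restores the literal reading.
- The package is organised as a simulator library with a thin CLI; the
  statsmodels-style Model/Results shape is used where data are actually
  fitted (`KineticsModel` → `FitResult` with `summary()`/`conf_int()`).
- Test problem sizes (scan grids, replicate counts, seed counts in the
  consistency and coverage checks) are scaled to keep the suite fast;
  the checks are calibration sanity checks, not coverage theorems.

## Known limitations

- No gas phase, oxygen transfer, pH or temperature dynamics; cultures
  are assumed fully aerated and buffered.
- Byproduct yields saturating the mass bound overstate overflow carbon;
  with realistic yields the famine food pools, and hence the
  coexistence boundary of the scan, shift.
- Single deterministic metabolic state per species: no phenotypic
  heterogeneity or stochastic switching.
- Fractions are mass fractions; cell-count observables require a
  conversion factor the package does not assume.
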