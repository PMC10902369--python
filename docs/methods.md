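# Methods

## Forward lung model

The lung is modelled as `n` parallel alveolar compartments of equal volume
V_i = ELV/n behind one series deadspace V_D, ventilated tidally at rate RR
with tidal volume V_T.  Compartment i receives the alveolar tidal share
ΔV_i = s_i·V_i·(V_T − V_D), where the specific ventilations s_i are
normalised so Σ s_i V_i = 1.  The tracer observable is simulated by a
per-breath discrete-time recursion, in fixed order:

1. **Inspiration.**  Each compartment first re-inspires its share
   d_i = V_D·ΔV_i/(V_T − V_D) of deadspace gas (at the previous mixed
   end-expiratory fraction — the gas that filled the airway at
   end-expiration), then fresh gas at F_I(t) = F₀ + A·sin(2πt/T), diluting
   its content over V_i + d_i + ΔV_i.
2. **Uptake.**  Tracer is removed to blood over one breath as the exact
   solution of V·dC/dt = −λ·q_i·(C − C_v) at the inflated volume, i.e.
   multiplication by g_i = exp(−λ·q_i·τ/V_insp,i) when C_v = 0.
3. **Expiration.**  The mixed end-expiratory fraction is the flow-weighted
   mean F_ET = Σ ΔV_i C_i / Σ ΔV_i; the deadspace refills with it.

A discrete recursion rather than a continuous ODE was chosen because the
measurement is breath-synchronous and the recursion conserves tracer mass
*exactly* (the tests verify per-breath closure to 1e−9 relative).  With this
choice the one-compartment step washin is geometric with per-breath ratio
(ELV + V_D)/(ELV + V_T): deadspace rebreathing makes the lung look larger by
V_D, which the inversion below accounts for consistently.

Model closures the measurement principle does not fix, with defaults:

| parameter | default | meaning / rationale |
|---|---|---|
| λ (blood–gas partition) | 0.47 | N₂O solubility; sets uptake strength |
| C_v (mixed venous content) | 0 | no recirculation over a short test; exposed |
| n (compartments) | 50 | smooth discretization at low cost |
| F₀, A (forcing) | 0.05, 0.02 | low-dose tracer, amplitude well above noise |
| trace length | 3 periods @180 s, 6 @60 s | ≥2 periods for fitting after warm-up |
| warm-up discarded | 1 period @180 s, 2 @60 s | transient decays as ((ELV+V_D)/(ELV+V_T))^breaths |

Heterogeneity enters through deterministic quantile-midpoint discretization
of LogNormal(μ, LogSD) with μ chosen so the weights average to 1 — no Monte
Carlo, so the forward map ŷ(LogSD) is smooth and bit-reproducible.
Ventilation and perfusion weights are **independent** by default: both come
from the same quantile grid, with the perfusion weights assigned through a
fixed frozen permutation.  A `vq_correlation` parameter adds a
rank-correlated component for modelling ventilation–perfusion matching; it
is kept at 0 because correlated pairings were found to introduce likelihood
aliasing between LogSDv and LogSDp that degrades the (precise) ventilation
estimate, while independence keeps LogSDv estimation clean (see
*Identifiability*, below).

Because the recursion is linear and time-invariant, its steady-state
response is available in closed form: `frequency_response` eliminates the
per-compartment amplitudes analytically and returns the exact complex gain
at the forcing frequency, and `mean_gain` its zero-frequency (DC) limit.
The LogSD estimator uses this closed form as its forward model — it is the
exact limit of simulate-then-fit without the warm-up transient (tests assert
the two routes agree) and about three orders of magnitude faster.

## IST inversion

Least-squares projection of each channel onto {1, sin ωt, cos ωt} at the
known forcing frequency (the device controls the period exactly) yields the
mean, amplitude and phase of the inspired and expired signals on a common
absolute time axis; F_I is sampled at start-of-inspiration, F_ET at
end-expiration, so the one-breath reporting delay is part of the model gain.
Given the measured complex gain H, the one-compartment inversion solves

    g = H / (u·(a + b·H)),   u = e^{-iωτ}

for the unique ELV making g real (linear in ELV because a and b share the
denominator ELV + V_T), then reads Qp from g.  The DC gain M gives a second
perfusion recovery g₀ = M/(a + b·M) → Qp_mean.  Both inversions are closed
form; infeasible gains (amplitude ratio outside (0, 1], non-positive uptake
factor) raise errors that the estimator treats as infeasible points.  V_D is
a known input throughout (the generator provides it): the source method
reports deadspace as an output, but no algorithm for it is public, and
estimating it would confound the validation of the heterogeneity indices.

The per-period IST result is y_T = (ELV, Qp, Qp_mean).  The third component
was added after a linearized error analysis showed that with y = (ELV, Qp)
alone the perfusion width is unidentifiable at realistic noise: after the
reference-total anchoring (below), every oscillatory perfusion observable is
roughly an order of magnitude more sensitive to LogSDv than to LogSDp, so
small LogSDv errors alias into LogSDp at ~10×.  The mean expired level is
measured by the same fits at no extra cost, with ~20× less noise than the
amplitudes, and steady-state uptake efficiency carries first-order V/Q
mismatch information.

## LogSD estimation

The estimator minimises the L1 loss between measured and predicted IST
results at both periods.  Two design choices matter:

* **Total calibration.**  The single-compartment inversion underestimates
  the totals of a heterogeneous lung, so at every candidate (LogSDv, LogSDp)
  the model lung's true (ELV, Qp) are solved (2-D root in log-space,
  tolerance 1e−10) so that its *apparent* 180-s outputs equal the reference
  totals — the measured 180-s values, the least heterogeneity-biased ones.
  This keeps measurement and prediction on a common scale; naive fixed-point
  rescaling converges too slowly (contraction ≈ 0.35) and biases LogSDp.
* **Precision weighting.**  The estimator divides each residual component by
  its nominal 1σ measurement precision, obtained at runtime by delta-method
  propagation of the per-breath expirate noise through the least-squares fit
  (amplitude error σ√(2/N), mean error σ/√N) and the inversion Jacobians.
  Only the *relative* precisions matter (a common factor cancels in the
  argmin), so the estimator does not need to know the true noise level.
  Plain reference-total normalisation — kept as the default of the public
  `loss()` — lets the noisy oscillatory-Qp channel drown out the precise DC
  channel.

Optimisation is deterministic: a 13×13 grid over [0, 3]² followed by
Nelder–Mead from the best node (parameter tolerance 1e−3, no stochastic
restarts).  Infeasible points carry infinite loss; estimation fails only if
every grid node is infeasible.

### Identifiability of LogSDp (known limitation)

At 0.5% expirate noise the ventilation width is recovered with median
absolute error ≈ 0.04, but the perfusion width is not: the best achievable
(generalised-least-squares) precision across pairing choices is
σ(LogSDp) ≈ 0.5–0.8, and the likelihood is bimodal over much of the
parameter space, so single-test LogSDp estimates scatter over [0, 3].  This
is a property of the observable set (two periods plus the DC level, with
unknown true totals), not of the optimiser; it parallels the empirical
finding that perfusion heterogeneity indices correlate far more weakly with
CT than ventilation ones.  Cohort-level LogSDp *means* remain informative;
per-test trend concordance for LogSDp does not.

## Quantitative CT

Aeration compartments are closed integer HU bins exactly as conventionally
printed ([−1000, −901], [−900, −501], [−500, −101], [−100, +100]); HU below
−1000 clamps to −1000, masked voxels above +100 are tallied as excluded.
Volumes are voxel counts × voxel volume; tissue mass uses the air–water
mixture (gas = clamp(−HU/1000, 0, 1)) with water density 1 g/cm³.

The ring inhomogeneity index is computed on **gas fraction** (inflation),
with pathologic defined as ring-more-aerated-than-voxel: ring membership by
voxel-centre distance r₁ = 2.41 ≤ d ≤ r₂ = 3.675 mm honouring anisotropic
spacing (purely in-plane at 0.5×0.5×5 mm), the voxel gas fraction floored at
0.01 to keep dense atelectasis finite, and a voxel valid only when ≥ 50% of
its geometric ring lies inside the mask (border voxels are excluded from
H_CT).  H_CT is the pathologic:normal *ratio* (> 1.61 : ≤ 1.61) over valid
voxels.  The implementation is ring-kernel correlation; tests require exact
agreement with a brute-force triple-loop oracle.

## Synthetic cohort

The generator emulates the study conditions: 6 animals (weights 28–32 kg),
PEEP ladder 5→10→15→20→15→10→5 cmH₂O, two paired IST + CT measurements per
step, V_T = 10 mL/kg, RR 20–25/min, expirate noise 0.5% of F₀.  Ground-truth
trajectories are linear in PEEP with multiplicative per-animal jitter:
LogSDv spans ≈ 1.0 → 0.4 and LogSDp ≈ 1.5 → 1.2 across the ladder, ELV rises
(recruitment), Qp falls slightly (venous return), V_D/V_T rises; the
decremental limb differs from the incremental by a per-animal factor within
±4% (hysteresis < 10%).  The CT heterogeneity parameter is a monotone map of
LogSDv truth, so both modalities share one latent quantity — the premise the
concordance analysis is designed to test.

Synthetic CT volumes (64×64×16 at 0.5×0.5×5 mm, ellipsoidal mask) hold an
aerated background (≈ −820 HU, correlated field + speckle); the latent
parameter sets the *extent* of patchy dependent collapse (top 0.4·param
quantile of depth-plus-blob potential jumps to near water density) and a
nondependent over-distension band.  A/N, O/N and H_CT all rise monotonically
with the parameter.  All randomness derives from seed-sequence streams keyed
by (seed, animal, step, repeat), so every artifact regenerates bit-for-bit
in isolation.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: anatomical lung shape, registration error between
PEEP levels, beam-hardening or reconstruction texture in HU, correlated
(non-iid) sensor noise, recirculating tracer, intra-breath gas transport,
and real V/Q microstructure beyond a two-parameter log-normal family.

## Statistics

Summary statistics use the population-SD convention (divide by n), which
reproduces the printed baseline-table SDs where the sample convention does
not; rounding is half-away-from-zero.  The Pearson matrix is
pairwise-complete with two-sided p-values from the t transform, computed on
per-step averages of repeated measurements.  Per-animal regressions are OLS;
the "overall" row is pooled OLS over all animals (a deliberate, labelled
simplification of a random-effects fit).  Four-quadrant concordance excludes
the axis-aligned rectangle |Δx| < 0.15·max|Δx| ∧ |Δy| < 0.15·max|Δy|, counts
pairs with Δx·Δy > 0 among the rest (pairs exactly on an axis count as
discordant — conservative), and reports slope/R² from OLS over all pairs.

## Problem sizes

Default analyses use the 6-animal cohort (84 paired tests), 50-compartment
lungs, 64×64×16 CT volumes and a 13×13 LogSD grid; the full pipeline runs in
about two minutes, dominated by the 84 LogSD fits (~1 s each).
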