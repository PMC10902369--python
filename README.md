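# istct — bedside lung-heterogeneity estimation vs quantitative CT

`istct` implements, end to end, the comparison of two bedside estimators of
lung heterogeneity based on the **inspired sinewave technique (IST)** with the
gold-standard **quantitative-CT** analysis, on fully synthetic porcine-ARDS
cohorts.  It is written for researchers in cardiopulmonary physiology and
quantitative lung imaging who want a tested, reproducible reference
implementation of the whole chain: forward lung simulation, parameter
inversion, CT voxel analysis and the trend-concordance statistics used to
compare the two modalities across a PEEP titration.

## The models and indices

**Forward model.** The lung is `n` parallel alveolar compartments behind a
series deadspace V_D.  Specific ventilation s_i (ventilation per unit
compartment volume) and perfusion q_i are log-normally distributed across
compartments with widths **LogSDv** and **LogSDp** — the heterogeneity
parameters.  A soluble tracer (N₂O, blood–gas partition coefficient
λ = 0.47) is forced sinusoidally in the inspired gas,
F_I(t) = F₀ + A·sin(2πt/T), at periods T = 180 s and 60 s; a per-breath
mass-conserving recursion (inspire → blood uptake → expire) yields the mixed
end-expiratory fraction F_ET per breath.

**IST inversion.** Treating the measured lung as a *single* compartment, the
steady-state complex gain at the forcing frequency is

    H(ω) = e^{-iωτ} · g·a / (1 − g·b·e^{-iωτ}),
    a = (V_T−V_D)/(ELV+V_T),  b = (ELV+V_D)/(ELV+V_T),
    g = exp(−λ·Qp·τ/(ELV+V_T)),   τ = breath duration,

which inverts in closed form for the effective lung volume ELV and pulmonary
blood flow Qp (the requirement that g be real makes ELV *linear* in the
measured gain).  The mean expired level gives a second, low-noise perfusion
estimate Qp_mean through the DC gain.  Applied to a heterogeneous lung these
apparent values depend on the forcing period, which defines the two IST
heterogeneity methods:

* **ratio indices** — H_IST,v = ELV₁₈₀/ELV₆₀ and H_IST,p = Qp₆₀/Qp₁₈₀, both
  1.0 for a homogeneous lung;
* **LogSD indices** — fit the multi-compartment simulator ŷ(LogSD) to the
  measured IST results y by minimising the L1 loss
  L(LogSD) = |y₁₈₀ − ŷ(LogSD)| + |y₆₀ − ŷ(LogSD)|; the fitted widths
  (LogSDv, LogSDp) are the heterogeneity readout.

**Quantitative CT.**  Masked voxels are classified by HU into over-distended
[−1000, −901], normally aerated [−900, −501], poorly aerated [−500, −101] and
atelectatic [−100, +100] compartments (ratios A/N, O/N; gas/tissue masses via
the air–water mixture gas = −HU/1000).  Per-voxel inhomogeneity compares each
voxel's gas fraction with the mean gas fraction of a surrounding geometric
ring of radii 2.41–3.675 mm; voxels whose index exceeds 1.61 are pathologic,
and **H_CT** is the pathologic:normal voxel ratio.

**Statistics.**  Pearson matrix over per-step-averaged indices, per-animal and
pooled OLS of each IST index on H_CT, and four-quadrant concordance of paired
PEEP-induced changes (ΔH_IST vs ΔH_CT) with a 15%-of-maximum exclusion zone.

## Worked example

```python
from istct.lung import build_lung, simulate
from istct.ist import recover_ist, heterogeneity_ratios
from istct.logsd import MeasurementVector, estimate_logsd
from istct.settings import SimSettings

s = SimSettings()
lung = build_lung(elv_true=900, vd=150, qp_true=3400,
                  log_sd_v=1.0, log_sd_p=1.5, n=50)
res = {}
for T in (180.0, 60.0):
    trace = simulate(lung, s.forcing(T, VT=300, RR=25))
    res[T] = recover_ist(trace, warmup_periods=s.warmup_periods[T])
h = heterogeneity_ratios(res[180.0], res[60.0])
mv = MeasurementVector(
    y180=(res[180.0].ELV, res[180.0].Qp, res[180.0].Qp_mean),
    y60=(res[60.0].ELV, res[60.0].Qp, res[60.0].Qp_mean),
    elv_ref=res[180.0].ELV, qp_ref=res[180.0].Qp, vd=150, VT=300, RR=25)
est = estimate_logsd(mv)
```

With a true 900 mL, 3.4 L/min lung at (LogSDv, LogSDp) = (1.0, 1.5) this
prints:

```
T=180s: ELV=706 mL  Qp=2197 mL/min  Qp_mean=1806 mL/min
T=60s:  ELV=598 mL  Qp=3340 mL/min  Qp_mean=1803 mL/min
h_ratio_v = 1.181, h_ratio_p = 1.520
LogSDv = 1.00, LogSDp = 1.50
```

The single-compartment inversion *underestimates* the true volume, more so at
the faster period (706 vs 598 mL) — that frequency dependence is exactly what
the ratio index encodes — and the simulation fit recovers the generating
widths.

## The analysis

Numbered drivers under `analysis/` run the study on the default synthetic
cohort (6 animals, PEEP ladder 5→10→15→20→15→10→5 cmH₂O, two paired IST + CT
measurements per step) and write their tables under `results/`:

```bash
python analysis/01_simulate_cohort.py --seed 1   # traces + CT volumes
python analysis/02_recover_ist.py                # ELV/Qp + ratio indices
python analysis/03_fit_logsd.py                  # LogSD fits (slowest)
python analysis/04_analyze_ct.py                 # aeration + H_CT
python analysis/05_compare.py                    # stats + figures
```

On the default cohort the ventilation indices track the CT gold standard
closely (Pearson r ≈ 0.95–0.98 against H_CT; four-quadrant concordance
97–100%), perfusion indices are markedly weaker — the LogSDp fit is at the
identifiability limit of the two-period measurement (see
`docs/methods.md`) — and all CT and IST heterogeneity indices fall as PEEP
recruits the lung while V_D/V_T rises.

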