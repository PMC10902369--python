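"""Synthetic porcine-ARDS cohort generator.

Emulates the study conditions of a saline-lavage pig PEEP-titration
experiment: 6 animals, PEEP ladder 5-10-15-20-15-10-5 cmH2O, two paired
IST + CT measurements per step.  Ground-truth heterogeneity falls as PEEP
rises (LogSDv spanning about 1.0 at PEEP 5 down to 0.4 at PEEP 20, LogSDp
1.5 down to 1.2), the incremental and decremental limbs differ by well
under 10%, and both modalities are driven by one latent heterogeneity so
that downstream trend-concordance analyses have a defined truth.

Everything is a deterministic function of (seed, protocol): per-animal
jitters and measurement noise come from seed-sequence streams keyed by
(animal, step, repeat), so any record can be regenerated in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .ctquant import CTVolume
from .ist import HeterogeneityIndices, ISTResult, heterogeneity_ratios, recover_ist
from .logsd import MeasurementVector
from .lung import BreathTrace, build_lung, simulate
from .settings import SimSettings

__all__ = [
    "ProtocolSpec",
    "ISTMeasurement",
    "generate_ground_truth",
    "generate_ist_measurements",
    "generate_ct_volume",
]


@dataclass(frozen=True)
class ProtocolSpec:
    """Study protocol for one synthetic cohort."""

    n_animals: int = 6
    weights_kg: tuple[float, ...] = (31, 32, 28, 28, 31, 32)
    peep_ladder: tuple[float, ...] = (5, 10, 15, 20, 15, 10, 5)
    repeats_per_step: int = 2
    vt_per_kg: float = 10.0  # mL/kg tidal volume
    rr_range: tuple[float, float] = (20.0, 25.0)  # breaths/min
    noise_sd: float = 0.005  # expirate noise, fraction of F0
    seed: int = 0
    sim: SimSettings = field(default_factory=SimSettings)
    ct_shape: tuple[int, int, int] = (64, 64, 16)
    ct_spacing: tuple[float, float, float] = (0.5, 0.5, 5.0)

    def __post_init__(self) -> None:
        if self.n_animals < 1 or self.repeats_per_step < 1:
            raise ValueError("need at least one animal and one repeat")
        if len(self.weights_kg) < self.n_animals:
            raise ValueError("need a weight per animal")
        lad = self.peep_ladder
        k = int(np.argmax(lad))
        up, down = lad[: k + 1], lad[k:]
        if list(up) != sorted(up) or list(down) != sorted(down, reverse=True):
            raise ValueError("peep_ladder must rise then fall")
        if self.noise_sd < 0 or self.vt_per_kg <= 0:
            raise ValueError("noise_sd must be >= 0 and vt_per_kg > 0")


@dataclass
class ISTMeasurement:
    """One paired two-period IST test of one animal at one protocol step."""

    animal: int
    step: int
    peep: float
    limb: str
    repeat: int
    traces: dict[float, BreathTrace]
    mv: MeasurementVector
    r180: ISTResult
    r60: ISTResult
    ratios: HeterogeneityIndices


def _animal_rng(spec: ProtocolSpec, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([spec.seed, *key]))


def generate_ground_truth(spec: ProtocolSpec) -> pd.DataFrame:
    """Per-(animal, step) ground truth table.

    Base trajectories (PEEP p in cmH2O):

    * LogSDv = 1.0 - 0.04 (p - 5)   (1.0 at PEEP 5 -> 0.4 at PEEP 20)
    * LogSDp = 1.5 - 0.02 (p - 5)   (1.5 -> 1.2)
    * ELV    = weight * (20 + 0.8 (p - 5)) mL      (recruitment)
    * Qp     = weight * (120 - 1.5 (p - 5)) mL/min (venous-return fall)
    * V_D    = VT * (0.30 + 0.006 (p - 5))         (airway distension)

    with multiplicative per-animal jitter and a per-animal decremental-limb
    factor within +/-4% (hysteresis under 10%).  The CT heterogeneity
    parameter is a monotone map of LogSDv so both modalities share one
    latent truth.
    """
    peak = int(np.argmax(spec.peep_ladder))
    rows = []
    for a in range(spec.n_animals):
        rng = _animal_rng(spec, a, 0)
        w = spec.weights_kg[a]
        vt = spec.vt_per_kg * w
        rr = float(rng.uniform(*spec.rr_range))
        j_lsv = 1.0 + rng.normal(0, 0.05)
        j_lsp = 1.0 + rng.normal(0, 0.04)
        j_elv = 1.0 + rng.normal(0, 0.05)
        j_qp = 1.0 + rng.normal(0, 0.08)
        limb_f = 1.0 + rng.uniform(-0.04, 0.04)
        for s, p in enumerate(spec.peep_ladder):
            limb = "incremental" if s <= peak else "decremental"
            f = limb_f if limb == "decremental" else 1.0
            lsv = max(0.05, (1.0 - 0.04 * (p - 5)) * j_lsv * f)
            lsp = max(0.05, (1.5 - 0.02 * (p - 5)) * j_lsp * f)
            rows.append(
                {
                    "animal": a,
                    "step": s,
                    "peep": float(p),
                    "limb": limb,
                    "log_sd_v_true": lsv,
                    "log_sd_p_true": lsp,
                    "elv_true": w * (20.0 + 0.8 * (p - 5)) * j_elv,
                    "qp_true": w * (120.0 - 1.5 * (p - 5)) * j_qp,
                    "vd_true": vt * (0.30 + 0.006 * (p - 5)),
                    "ct_param": float(np.clip((lsv - 0.2) / 1.0, 0.0, 1.0)),
                    "vt": vt,
                    "rr": rr,
                }
            )
    return pd.DataFrame(rows)


def generate_ist_measurements(
    truth: pd.DataFrame,
    spec: ProtocolSpec,
) -> list[ISTMeasurement]:
    """Simulate and recover all paired IST tests of a cohort.

    For each (animal, step, repeat): build the ground-truth lung, run the
    tidal simulator at both sinusoid periods, add iid Gaussian expirate
    noise of sd ``noise_sd * F0``, fit and invert.  Deterministic per
    (seed, spec); ``noise_sd = 0`` makes repeats identical.
    """
    sim = spec.sim
    out: list[ISTMeasurement] = []
    for row in truth.itertuples():
        lung = build_lung(
            row.elv_true,
            row.vd_true,
            row.qp_true,
            row.log_sd_v_true,
            row.log_sd_p_true,
            n=sim.n_compartments,
            lambda_b=sim.lambda_b,
            vq_correlation=sim.vq_correlation,
        )
        for rep in range(spec.repeats_per_step):
            traces: dict[float, BreathTrace] = {}
            y: dict[float, tuple[float, float, float]] = {}
            results: dict[float, ISTResult] = {}
            for t_idx, T in enumerate(sim.periods):
                trace = simulate(lung, sim.forcing(T, row.vt, row.rr))
                if spec.noise_sd > 0:
                    rng = _animal_rng(spec, row.animal, row.step, rep, t_idx, 1)
                    trace.F_ET = trace.F_ET + rng.normal(
                        0.0, spec.noise_sd * sim.F0, len(trace)
                    )
                res = recover_ist(
                    trace,
                    lambda_b=sim.lambda_b,
                    warmup_periods=sim.warmup_periods[T],
                )
                traces[T] = trace
                results[T] = res
                y[T] = (res.ELV, res.Qp, res.Qp_mean)
            mv = MeasurementVector(
                y180=y[180.0],
                y60=y[60.0],
                elv_ref=y[180.0][0],
                qp_ref=y[180.0][1],
                vd=row.vd_true,
                VT=row.vt,
                RR=row.rr,
            )
            out.append(
                ISTMeasurement(
                    animal=row.animal,
                    step=row.step,
                    peep=row.peep,
                    limb=row.limb,
                    repeat=rep,
                    traces=traces,
                    mv=mv,
                    r180=results[180.0],
                    r60=results[60.0],
                    ratios=heterogeneity_ratios(results[180.0], results[60.0]),
                )
            )
    return out


def generate_ct_volume(
    truth_row,
    spec: ProtocolSpec,
    repeat: int = 0,
) -> CTVolume:
    """Synthetic end-expiratory CT volume for one (animal, step, repeat).

    An ellipsoidal lung mask holds a smooth aerated background (about
    -820 HU with a spatially correlated Gaussian field and fine speckle).
    The latent heterogeneity parameter (0..1, mapped from LogSDv truth)
    controls the *extent* of patchy dependent atelectasis: voxels whose
    gravitational potential (depth along the gravity axis plus a correlated
    regional field) exceeds a param-dependent quantile collapse to near
    water density, so the atelectatic fraction is about 0.4 * param and the
    sharp aerated/collapsed interfaces that the voxel-ring index flags grow
    with it.  A nondependent over-distension band below -900 HU also scales
    with param.  All three CT readouts (A/N, O/N, H_CT) therefore rise with
    the latent parameter and fall as PEEP recruits the lung.  Deterministic
    per (seed, animal, step, repeat); the repeat only reseeds the speckle.
    """
    nx, ny, nz = spec.ct_shape
    param = float(truth_row.ct_param)
    rng_field = _animal_rng(spec, int(truth_row.animal), int(truth_row.step), 2)
    rng_speckle = _animal_rng(
        spec, int(truth_row.animal), int(truth_row.step), int(repeat), 3
    )

    x, y, z = np.meshgrid(
        np.linspace(-1, 1, nx), np.linspace(-1, 1, ny), np.linspace(-1, 1, nz),
        indexing="ij",
    )
    mask = (x / 0.85) ** 2 + (y / 0.85) ** 2 + (z / 0.9) ** 2 <= 1.0

    base = gaussian_filter(rng_field.standard_normal(spec.ct_shape), (4.0, 4.0, 1.0))
    base = base / max(base.std(), 1e-12)
    hu = -820.0 + 25.0 * base + 12.0 * rng_speckle.standard_normal(spec.ct_shape)

    depth = (y + 1.0) / 2.0  # gravity along +y (dependent region at depth 1)
    # nondependent over-distension band
    hu = hu - 130.0 * param * (1.0 - depth) ** 2

    # patchy dependent collapse: top 0.4*param quantile of the potential
    atel_frac = 0.40 * param
    if atel_frac > 0:
        blob = gaussian_filter(rng_field.standard_normal(spec.ct_shape), (3.0, 3.0, 1.0))
        blob = blob / max(blob.std(), 1e-12)
        potential = depth + 0.35 * blob
        thr = np.quantile(potential[mask], 1.0 - atel_frac)
        atel = mask & (potential >= thr)
        hu[atel] = -70.0 + 35.0 * rng_speckle.standard_normal(int(atel.sum()))

    hu = np.clip(np.rint(hu), -1000, 100).astype(np.int16)
    return CTVolume(hu=hu, mask=mask, spacing=spec.ct_spacing)
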