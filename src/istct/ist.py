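"""Recovery of IST parameters (ELV, Qp) from a breath trace.

The inspired sinewave technique drives the lung with a sinusoidally
modulated tracer fraction and observes the expired response.  Treating the
lung as a single well-mixed compartment behind a series deadspace, the
per-breath recursion in :mod:`istct.lung` is a linear time-invariant system
sampled at the breath rate, so the steady-state expired signal is a sinusoid
at the forcing frequency with a complex gain

    H(w) = e^{-i w tau} * g a / (1 - g b e^{-i w tau})

where tau is the breath duration, a = (VT - V_D)/(ELV + VT),
b = (ELV + V_D)/(ELV + VT) and g = exp(-lambda_b Qp tau / (ELV + VT)) is the
per-breath soluble-uptake factor.  Given the measured complex gain the two
real conditions (amplitude ratio and phase lag) invert in closed form for
ELV and lambda_b*Qp: requiring g to be real makes ELV linear in the measured
quantities, and g then yields Qp.

Applied to a *heterogeneous* lung this single-compartment inversion returns
apparent values that depend on the forcing period; the ratios ELV180/ELV60
and Qp60/Qp180 are the IST heterogeneity ratio indices.
"""

from __future__ import annotations

import cmath
import math
from dataclasses import dataclass

import numpy as np

from .lung import BreathTrace

__all__ = [
    "SineFit",
    "ISTResult",
    "HeterogeneityIndices",
    "fit_sinusoid",
    "invert_gain",
    "invert_dc",
    "invert_single_compartment",
    "recover_ist",
    "heterogeneity_ratios",
]


@dataclass(frozen=True)
class SineFit:
    """Least-squares sinusoid fit ``y = mean + amplitude * sin(w t + phase)``."""

    mean: float
    amplitude: float
    phase: float  # in (-pi, pi]
    residual_rms: float
    n_used: int

    @property
    def complex_amp(self) -> complex:
        """Z such that ``y = mean + Re(Z e^{i w t})`` on the absolute time axis."""
        # y = m + a sin(wt + phi) = m + a cos(phi) sin(wt) + a sin(phi) cos(wt)
        # = m + Re((r - i p) e^{iwt}) with p = a cos(phi), r = a sin(phi)
        return self.amplitude * (math.sin(self.phase) - 1j * math.cos(self.phase))


@dataclass(frozen=True)
class ISTResult:
    """Recovered IST parameters at one forcing period.

    ``Qp`` comes from the oscillatory (AC) response at the forcing period;
    ``Qp_mean`` from the mean (DC) expired level, i.e. steady-state uptake
    efficiency.  The two agree for a homogeneous lung and split apart as
    ventilation-perfusion heterogeneity grows.
    """

    period_T: float
    ELV: float
    Qp: float
    V_D: float
    insp_fit: SineFit
    exp_fit: SineFit
    Qp_mean: float = 0.0

    def __post_init__(self) -> None:
        if self.ELV <= 0:
            raise ValueError("ELV must be positive")
        if self.Qp < 0 or self.Qp_mean < 0:
            raise ValueError("Qp must be >= 0")
        if self.exp_fit.amplitude > self.insp_fit.amplitude * (1 + 1e-9):
            raise ValueError("expired amplitude exceeds inspired amplitude")


@dataclass
class HeterogeneityIndices:
    """IST heterogeneity indices: frequency ratios, LogSD fits added later."""

    h_ratio_v: float  # ELV180 / ELV60
    h_ratio_p: float  # Qp60 / Qp180
    log_sd_v: float | None = None
    log_sd_p: float | None = None

    def __post_init__(self) -> None:
        if self.h_ratio_v <= 0 or self.h_ratio_p <= 0:
            raise ValueError("heterogeneity ratios must be positive")


def fit_sinusoid(
    trace: BreathTrace,
    channel: str = "F_ET",
    period_T: float | None = None,
    warmup_periods: float = 1.0,
) -> SineFit:
    """Project one trace channel onto {1, sin, cos} at the known forcing period.

    The first ``warmup_periods`` forcing periods are discarded (transient
    decay); the remainder must span at least two periods.  ``F_I`` samples are
    taken at start-of-inspiration times, ``F_ET`` at end-expiration times, so
    the fitted phases live on a common absolute time axis.
    """
    if period_T is None:
        period_T = trace.period_T
    if channel == "F_I":
        t, y = trace.t_insp, trace.F_I
    elif channel == "F_ET":
        t, y = trace.t_end, trace.F_ET
    else:
        raise ValueError("channel must be 'F_I' or 'F_ET'")

    t0 = trace.t_insp[0] + warmup_periods * period_T
    keep = t >= t0
    t, y = t[keep], y[keep]
    # n samples tau apart cover a span of n*tau: credit one breath beyond t[-1]-t[0]
    if len(t) < 4 or (t[-1] - t[0]) + 60.0 / trace.RR < 2.0 * period_T - 1e-9:
        raise ValueError("trace too short: need >= 2 forcing periods after warm-up")

    w = 2.0 * math.pi / period_T
    X = np.column_stack([np.ones_like(t), np.sin(w * t), np.cos(w * t)])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    m, p, r = beta
    amp = math.hypot(p, r)
    phase = math.atan2(r, p)
    if phase <= -math.pi:
        phase += 2.0 * math.pi
    resid = y - X @ beta
    return SineFit(
        mean=float(m),
        amplitude=float(amp),
        phase=float(phase),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        n_used=len(t),
    )


def invert_gain(
    H: complex,
    VT: float,
    V_D: float,
    RR: float,
    lambda_b: float = 0.47,
    period_T: float = 180.0,
    tol: float = 1e-6,
) -> tuple[float, float]:
    """Closed-form inversion of the one-compartment frequency response.

    Writing H for the measured complex gain (expired over inspired complex
    amplitudes) and u = e^{-i w tau}, the model gives
    ``g = H / (u (a + b H))`` which must be real and in (0, 1].  Because a and
    b share the denominator ELV + VT, Im(g) = 0 reduces to a *linear*
    equation in ELV:

        ELV = -V_D - (VT - V_D) Im(H conj(u)) / (|H|^2 Im(conj(u)))

    after which ``Qp = -ln(g) (ELV + VT) / (lambda_b tau)``.

    Returns ``(ELV mL, Qp mL/min)``.  Raises on amplitude ratio outside
    (0, 1 + tol] or when the recovered ELV or uptake factor is infeasible.
    """
    if V_D >= VT:
        raise ValueError("V_D must be less than VT")
    ratio = abs(H)
    if ratio <= 1e-12 or ratio > 1 + tol:
        raise ValueError(f"no solution: expired/inspired amplitude ratio {ratio:.4g} outside (0, 1]")

    tau = 60.0 / RR
    w = 2.0 * math.pi / period_T
    u = cmath.exp(-1j * w * tau)

    im_ustar = math.sin(w * tau)  # Im(conj(u))
    if abs(im_ustar) < 1e-12:
        raise ValueError("degenerate forcing: breath rate aliases the forcing period")
    h_ustar = H * u.conjugate()
    elv = -V_D - (VT - V_D) * h_ustar.imag / ((abs(H) ** 2) * im_ustar)
    if elv <= 0:
        raise ValueError(f"no solution: recovered ELV {elv:.4g} mL not positive")

    a = (VT - V_D) / (elv + VT)
    b = (elv + V_D) / (elv + VT)
    g = H / (u * (a + b * H))
    # Im(g) = 0 holds by construction of elv; keep the real part.
    g_real = g.real
    if g_real <= 0:
        raise ValueError("no solution: uptake factor not positive")
    if g_real > 1 + tol:
        raise ValueError(f"no solution: uptake factor {g_real:.6g} exceeds 1")
    g_real = min(g_real, 1.0)
    qp = -math.log(g_real) * (elv + VT) / (lambda_b * tau / 60.0)
    return float(elv), float(qp)


def invert_dc(
    M: float,
    elv: float,
    VT: float,
    V_D: float,
    RR: float,
    lambda_b: float = 0.47,
    tol: float = 5e-3,
) -> float:
    """Recover Qp from the DC gain M = mean(F_ET)/mean(F_I), given ELV.

    ``M`` up to ``1 + tol`` (fit noise around a perfusionless lung) clamps
    to Qp = 0.

    At zero frequency the one-compartment model gives
    ``M = g0 a / (1 - g0 b)`` with the same a, b as the AC inversion, so
    ``g0 = M / (a + b M)`` in closed form and Qp follows from the uptake
    factor.  The mean levels are measured far more precisely than the
    oscillation amplitudes, making this the low-noise perfusion channel.
    """
    if not (0 < M <= 1 + tol):
        raise ValueError(f"no solution: DC gain {M:.4g} outside (0, 1]")
    if elv <= 0:
        raise ValueError("ELV must be positive")
    a = (VT - V_D) / (elv + VT)
    b = (elv + V_D) / (elv + VT)
    g0 = M / (a + b * M)
    if g0 <= 0:
        raise ValueError("no solution: DC uptake factor not positive")
    if g0 > 1 + tol:
        raise ValueError(f"no solution: DC uptake factor {g0:.6g} exceeds 1")
    g0 = min(g0, 1.0)
    tau = 60.0 / RR
    return float(-math.log(g0) * (elv + VT) / (lambda_b * tau / 60.0))


def invert_single_compartment(
    insp: SineFit,
    exp: SineFit,
    VT: float,
    V_D: float,
    RR: float,
    lambda_b: float = 0.47,
    period_T: float = 180.0,
    tol: float = 1e-6,
) -> tuple[float, float]:
    """Invert fitted inspired/expired sinusoids for (ELV, Qp).

    Thin wrapper over :func:`invert_gain`: forms the measured complex gain
    from the two fits (which live on a common absolute time axis) and applies
    the closed-form single-compartment inversion.
    """
    if insp.amplitude <= 0:
        raise ValueError("inspired amplitude must be positive")
    H = exp.complex_amp / insp.complex_amp
    return invert_gain(
        H, VT=VT, V_D=V_D, RR=RR, lambda_b=lambda_b, period_T=period_T, tol=tol
    )


def recover_ist(
    trace: BreathTrace,
    lambda_b: float = 0.47,
    warmup_periods: float = 1.0,
) -> ISTResult:
    """Fit both channels of a trace and invert for (ELV, Qp) at its period."""
    insp = fit_sinusoid(trace, "F_I", warmup_periods=warmup_periods)
    expf = fit_sinusoid(trace, "F_ET", warmup_periods=warmup_periods)
    elv, qp = invert_single_compartment(
        insp,
        expf,
        VT=trace.VT,
        V_D=trace.V_D,
        RR=trace.RR,
        lambda_b=lambda_b,
        period_T=trace.period_T,
    )
    qp_mean = invert_dc(
        expf.mean / insp.mean,
        elv,
        VT=trace.VT,
        V_D=trace.V_D,
        RR=trace.RR,
        lambda_b=lambda_b,
    )
    return ISTResult(
        period_T=trace.period_T,
        ELV=elv,
        Qp=qp,
        V_D=trace.V_D,
        insp_fit=insp,
        exp_fit=expf,
        Qp_mean=qp_mean,
    )


def heterogeneity_ratios(r180: ISTResult, r60: ISTResult) -> HeterogeneityIndices:
    """IST ratio heterogeneity indices ELV180/ELV60 and Qp60/Qp180.

    Both ratios equal 1 for a homogeneous lung and deviate from 1 as
    ventilation (resp. perfusion) heterogeneity grows.
    """
    if not (r180.period_T > r60.period_T):
        raise ValueError("first argument must be the longer-period result")
    if r60.ELV == 0 or r180.Qp == 0:
        raise ValueError("zero denominator in heterogeneity ratio")
    return HeterogeneityIndices(
        h_ratio_v=r180.ELV / r60.ELV,
        h_ratio_p=r60.Qp / r180.Qp,
    )
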