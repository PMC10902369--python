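"""Multi-compartment tidal-breathing simulator for an inert tracer gas.

The lung is modelled as ``n`` parallel alveolar compartments behind a common
series deadspace.  Specific ventilation (ventilation per unit compartment
volume) and perfusion are log-normally distributed across compartments; the
widths of those distributions (LogSDv, LogSDp) are the heterogeneity
parameters the rest of the pipeline tries to recover.  The tracer (N2O by
default) is soluble, so pulmonary blood flow removes it from each compartment
at a rate set by the blood-gas partition coefficient.

The simulation is a per-breath discrete-time recursion (inspire -> uptake ->
expire) rather than a continuous ODE: measurements are breath-synchronous and
the recursion conserves tracer mass exactly, which the tests verify.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

__all__ = [
    "LungModel",
    "SineForcing",
    "BreathTrace",
    "discretize_lognormal",
    "build_lung",
    "simulate",
    "frequency_response",
]

# Fixed coupling between the sorted ventilation and perfusion quantile grids.
# Drawn once from an arbitrary PCG stream and frozen so that independent
# (uncorrelated) v/q weights remain a deterministic function of (log_sd, n).
_PAIRING_SEED = 987654321


@dataclass(frozen=True)
class LungModel:
    """Ground-truth compartmental lung.

    Attributes
    ----------
    V_i : ndarray
        Alveolar volume per compartment (mL); ``sum(V_i)`` is the true ELV.
    s_i : ndarray
        Specific ventilation per compartment, normalised so that
        ``sum(s_i * V_i) == 1``; compartment ``i`` receives the share
        ``s_i * V_i`` of the alveolar tidal volume.
    q_i : ndarray
        Perfusion per compartment (mL/min); ``sum(q_i)`` is the true Qp.
    V_D : float
        Series (conducting-airway) deadspace volume (mL).
    lambda_b : float
        Blood-gas partition coefficient of the tracer (0.47 for N2O).
    C_v : float
        Mixed-venous tracer content (fraction); 0 means no recirculation.
    """

    V_i: np.ndarray
    s_i: np.ndarray
    q_i: np.ndarray
    V_D: float
    lambda_b: float = 0.47
    C_v: float = 0.0

    def __post_init__(self) -> None:
        V_i = np.asarray(self.V_i, dtype=float)
        s_i = np.asarray(self.s_i, dtype=float)
        q_i = np.asarray(self.q_i, dtype=float)
        if not (V_i.shape == s_i.shape == q_i.shape):
            raise ValueError("V_i, s_i, q_i must have matching shapes")
        if np.any(V_i < 0) or np.any(s_i < 0) or np.any(q_i < 0):
            raise ValueError("volumes, specific ventilations and perfusions must be >= 0")
        if self.V_D < 0:
            raise ValueError("deadspace must be >= 0")
        share = float(np.sum(s_i * V_i))
        if not np.isclose(share, 1.0, rtol=1e-8, atol=1e-10):
            raise ValueError(f"sum(s_i * V_i) must be 1 (got {share:.6g})")
        object.__setattr__(self, "V_i", V_i)
        object.__setattr__(self, "s_i", s_i)
        object.__setattr__(self, "q_i", q_i)

    @property
    def n_compartments(self) -> int:
        return self.V_i.size

    @property
    def elv_true(self) -> float:
        return float(np.sum(self.V_i))

    @property
    def qp_true(self) -> float:
        return float(np.sum(self.q_i))


@dataclass(frozen=True)
class SineForcing:
    """Sinusoidal inspired-tracer forcing.

    ``F_I(t) = F0 + A * sin(2 pi t / period_T)`` sampled at the start of each
    inspiration.  The forcing period need not be a multiple of the breath
    duration; phase accumulates continuously.
    """

    period_T: float  # s
    F0: float = 0.05
    A: float = 0.01
    RR: float = 20.0  # breaths/min
    VT: float = 300.0  # mL
    n_breaths: int = 200

    def __post_init__(self) -> None:
        if self.period_T <= 0 or self.RR <= 0 or self.VT <= 0 or self.n_breaths < 1:
            raise ValueError("period_T, RR, VT must be positive; n_breaths >= 1")
        if not (0 < self.A <= self.F0):
            raise ValueError("need 0 < A <= F0")
        if self.F0 + self.A > 1:
            raise ValueError("F0 + A must not exceed 1")

    @property
    def tau(self) -> float:
        """Breath duration (s)."""
        return 60.0 / self.RR

    def inspired(self, t: np.ndarray | float) -> np.ndarray | float:
        return self.F0 + self.A * np.sin(2.0 * np.pi * np.asarray(t) / self.period_T)


@dataclass
class BreathTrace:
    """Per-breath tracer fractions from one sinusoidal run.

    ``t_insp`` is the start-of-inspiration time at which ``F_I`` applies;
    ``t_end`` the end-expiration time at which ``F_ET`` (the mixed
    end-expiratory fraction, the measured output) is recorded.
    """

    t_insp: np.ndarray
    t_end: np.ndarray
    F_I: np.ndarray
    F_ET: np.ndarray
    period_T: float
    VT: float
    RR: float
    V_D: float
    balance: dict | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        n = len(self.F_I)
        if not (len(self.t_insp) == len(self.t_end) == len(self.F_ET) == n):
            raise ValueError("trace arrays must have equal length")
        if np.any(self.F_I < 0) or np.any(self.F_I > 1):
            raise ValueError("F_I outside [0, 1]")

    def __len__(self) -> int:
        return len(self.F_I)

    def to_csv(self, path) -> None:
        """Write the trace as CSV with columns time_s, F_I, F_ET."""
        import pandas as pd

        pd.DataFrame(
            {"time_s": self.t_end, "F_I": self.F_I, "F_ET": self.F_ET}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, period_T: float, VT: float, RR: float, V_D: float) -> "BreathTrace":
        import pandas as pd

        df = pd.read_csv(path)
        t_end = df["time_s"].to_numpy(float)
        tau = 60.0 / RR
        return cls(
            t_insp=t_end - tau,
            t_end=t_end,
            F_I=df["F_I"].to_numpy(float),
            F_ET=df["F_ET"].to_numpy(float),
            period_T=period_T,
            VT=VT,
            RR=RR,
            V_D=V_D,
        )


def discretize_lognormal(log_sd: float, n: int) -> np.ndarray:
    """Deterministic quantile-midpoint discretization of LogNormal(mu, log_sd).

    Returns ``n`` weights taken at the quantile midpoints ``(k - 1/2)/n`` with
    ``mu`` chosen so the weights average exactly to 1.  No sampling is
    involved, so repeated calls are bit-for-bit identical -- this keeps the
    simulated observable a smooth deterministic function of ``log_sd``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if log_sd < 0:
        raise ValueError("log_sd must be >= 0")
    if log_sd == 0:
        return np.ones(n)
    p = (np.arange(n) + 0.5) / n
    w = np.exp(log_sd * norm.ppf(p))
    return w / w.mean()


def _pairing_permutation(n: int) -> np.ndarray:
    """Frozen permutation decorrelating the sorted v and q quantile grids."""
    return np.random.default_rng(_PAIRING_SEED).permutation(n)


def build_lung(
    elv_true: float,
    vd: float,
    qp_true: float,
    log_sd_v: float,
    log_sd_p: float,
    n: int = 50,
    lambda_b: float = 0.47,
    C_v: float = 0.0,
    vq_correlation: float = 0.0,
) -> LungModel:
    """Assemble an ``n`` equal-volume compartment lung with log-normal
    specific ventilations (width ``log_sd_v``) and perfusions (``log_sd_p``).

    By default ventilation and perfusion weights are independent: the
    perfusion weights come from the same deterministic quantile grid but are
    assigned to compartments through a fixed frozen permutation.  A nonzero
    ``vq_correlation`` adds a rank-correlated component (Gaussian-mixture
    construction on the quantile grid) for modelling ventilation-perfusion
    matching.  Everything is a deterministic function of the arguments.
    """
    if elv_true <= 0 or qp_true < 0 or vd < 0:
        raise ValueError("elv_true must be > 0; qp_true, vd >= 0")
    if not (-1.0 <= vq_correlation <= 1.0):
        raise ValueError("vq_correlation must lie in [-1, 1]")
    w_v = discretize_lognormal(log_sd_v, n)
    # perfusion log-weights: rho * (ventilation z-grid) + sqrt(1-rho^2) *
    # (independent z-grid via the frozen permutation), scaled to log_sd_p
    rho = vq_correlation
    if log_sd_p == 0 or n == 1:
        w_p = np.ones(n)
    else:
        p = (np.arange(n) + 0.5) / n
        z = norm.ppf(p)
        z_perm = z[_pairing_permutation(n)]
        w_p = np.exp(log_sd_p * (rho * z + np.sqrt(1.0 - rho**2) * z_perm))
        w_p /= w_p.mean()
    V_i = np.full(n, elv_true / n)
    # sum(s_i * V_i) = 1 given mean(w_v) = 1 and equal volumes
    s_i = w_v / elv_true
    q_i = qp_true * w_p / w_p.sum()
    return LungModel(V_i=V_i, s_i=s_i, q_i=q_i, V_D=vd, lambda_b=lambda_b, C_v=C_v)


def simulate(
    lung: LungModel,
    forcing: SineForcing,
    init: str = "equilibrium",
    track_balance: bool = False,
) -> BreathTrace:
    """Run the per-breath tracer recursion and return the breath trace.

    Breath ``m`` (duration tau = 60/RR) proceeds in order:

    1. inspiration -- each compartment receives its share
       ``d_i = V_D * dV_i / (VT - V_D)`` of re-inspired deadspace gas (at the
       previous mixed end-expiratory fraction) followed by fresh gas at
       ``F_I(t_m)``, diluting its content over ``V_i + d_i + dV_i`` with
       ``dV_i = s_i * V_i * (VT - V_D)``;
    2. uptake -- tracer is removed to blood over one breath, the exact
       solution of ``V dC/dt = -lambda_b q_i (C - C_v)`` at the inflated
       volume;
    3. expiration -- the mixed end-expiratory fraction is the flow-weighted
       mean ``F_ET = sum(dV_i C_i) / sum(dV_i)``; the deadspace refills with
       that gas.

    ``init='equilibrium'`` starts compartments at the steady state of the DC
    component (mean forcing ``F0``), so only the small AC transient remains to
    decay during warm-up; ``init='zero'`` starts with no tracer anywhere.
    """
    if forcing.VT <= lung.V_D:
        raise ValueError("no alveolar ventilation: VT must exceed deadspace V_D")

    n_b = forcing.n_breaths
    tau = forcing.tau
    VT, V_D = forcing.VT, lung.V_D
    V = lung.V_i
    dV = lung.s_i * V * (VT - V_D)  # alveolar tidal share; sums to VT - V_D
    w = dV / dV.sum()
    d = V_D * w  # re-inspired deadspace share
    V_insp = V + d + dV
    # exact per-breath uptake factor at the inflated volume
    g = np.exp(-lung.lambda_b * lung.q_i * (tau / 60.0) / V_insp)

    t_insp = np.arange(n_b) * tau
    t_end = t_insp + tau
    F_I = np.asarray(forcing.inspired(t_insp), dtype=float)

    C_v = lung.C_v
    if init == "equilibrium":
        # fixed point of the DC recursion with shared deadspace fraction F0:
        # per compartment C = g * [(V C + (d + dV) F0) / V_insp] has the
        # solution below only if the deadspace also sits at the compartment
        # mix; solve the coupled fixed point iteratively (fast contraction).
        C = np.full_like(V, forcing.F0)
        F_D = forcing.F0
        for _ in range(200):
            C_new = C_v + (((V * C + d * F_D + dV * forcing.F0) / V_insp) - C_v) * g
            F_D_new = float(np.sum(w * C_new))
            if np.max(np.abs(C_new - C)) < 1e-15 and abs(F_D_new - F_D) < 1e-15:
                C, F_D = C_new, F_D_new
                break
            C, F_D = C_new, F_D_new
    elif init == "zero":
        C = np.zeros_like(V)
        F_D = 0.0
    else:
        raise ValueError("init must be 'equilibrium' or 'zero'")

    F_ET = np.empty(n_b)
    if track_balance:
        moles_in = np.empty(n_b)
        moles_out = np.empty(n_b)
        uptake = np.empty(n_b)
        store = np.empty(n_b)
        store0 = float(np.sum(C * V)) + V_D * F_D

    for m in range(n_b):
        # 1. inspiration: deadspace gas first, then fresh gas at F_I
        C_insp = (V * C + d * F_D + dV * F_I[m]) / V_insp
        # 2. uptake to blood at the inflated volume
        C_post = C_v + (C_insp - C_v) * g
        # 3. expiration: flow-weighted alveolar mix; deadspace refills with it
        f_et = float(np.sum(w * C_post))
        if track_balance:
            moles_in[m] = VT * F_I[m]
            # mouth expirate: V_D of deadspace washout (fresh gas at F_I)
            # followed by VT - V_D of mixed alveolar gas
            moles_out[m] = V_D * F_I[m] + (VT - V_D) * f_et
            uptake[m] = float(np.sum(V_insp * (C_insp - C_post)))
            store[m] = float(np.sum(C_post * V)) + V_D * f_et
        C = C_post
        F_D = f_et
        F_ET[m] = f_et

    balance = None
    if track_balance:
        balance = {
            "moles_in": moles_in,
            "moles_out": moles_out,
            "uptake": uptake,
            "store": store,
            "store0": store0,
        }
    return BreathTrace(
        t_insp=t_insp,
        t_end=t_end,
        F_I=F_I,
        F_ET=F_ET,
        period_T=forcing.period_T,
        VT=VT,
        RR=forcing.RR,
        V_D=V_D,
        balance=balance,
    )


def frequency_response(
    lung: LungModel,
    period_T: float,
    VT: float,
    RR: float,
) -> complex:
    """Exact steady-state complex gain of the breath recursion at the forcing
    frequency, in the measurement convention (F_ET recorded one breath after
    the F_I sample it responds to).

    The recursion in :func:`simulate` is linear and time-invariant, so its
    steady-state response to ``F_I = F0 + Re(Z e^{i w t})`` is a sinusoid with
    complex amplitude ``H * Z``.  Writing ``u = e^{-i w tau}``, eliminating
    the per-compartment amplitudes from

        Z_i = g_i (V_i Z_i u + d_i E u + dV_i Z) / V_insp_i,   E = sum(w_i Z_i)

    gives the mixed alveolar gain ``E/Z`` and, after the one-breath delay to
    end-expiration, ``H = u * (E/Z)``.  This is the same observable a
    noiseless :func:`simulate` + sinusoid fit converges to, without the
    warm-up transient (the tests verify the two routes agree).
    """
    if VT <= lung.V_D:
        raise ValueError("no alveolar ventilation: VT must exceed deadspace V_D")
    tau = 60.0 / RR
    w_ang = 2.0 * np.pi / period_T
    u = np.exp(-1j * w_ang * tau)
    V = lung.V_i
    dV = lung.s_i * V * (VT - lung.V_D)
    w = dV / dV.sum()
    d = lung.V_D * w
    V_insp = V + d + dV
    g = np.exp(-lung.lambda_b * lung.q_i * (tau / 60.0) / V_insp)
    D = V_insp - g * V * u
    s_dead = u * np.sum(w * g * d / D)
    s_fresh = np.sum(w * g * dV / D)
    return complex(u * s_fresh / (1.0 - s_dead))


def mean_gain(lung: LungModel, VT: float, RR: float) -> float:
    """Steady-state DC gain mean(F_ET)/mean(F_I) of the breath recursion.

    The zero-frequency limit of :func:`frequency_response`; it measures the
    steady-state soluble-tracer uptake efficiency, which ventilation-perfusion
    mismatch degrades at first order (high-perfusion, low-ventilation units
    strip tracer from a gas stream that carries little of it).
    """
    if VT <= lung.V_D:
        raise ValueError("no alveolar ventilation: VT must exceed deadspace V_D")
    tau = 60.0 / RR
    V = lung.V_i
    dV = lung.s_i * V * (VT - lung.V_D)
    w = dV / dV.sum()
    d = lung.V_D * w
    V_insp = V + d + dV
    g = np.exp(-lung.lambda_b * lung.q_i * (tau / 60.0) / V_insp)
    D = V_insp - g * V
    s_dead = np.sum(w * g * d / D)
    s_fresh = np.sum(w * g * dV / D)
    return float(s_fresh / (1.0 - s_dead))
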