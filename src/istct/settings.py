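"""Shared acquisition / simulation settings for the IST pipeline.

One IST test drives the lung at two sinusoid periods (180 s and 60 s).  The
same settings object parameterises both the synthetic measurement generator
and the simulation-based LogSD estimator, so predicted and measured IST
results share acquisition conventions (forcing amplitude, trace length,
warm-up) and discretization (compartment count) by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .lung import SineForcing

__all__ = ["SimSettings"]


@dataclass(frozen=True)
class SimSettings:
    """Acquisition and forward-model settings common to both periods.

    Defaults: mean inspired N2O fraction 5% with 2% sinusoidal amplitude;
    3 forcing periods recorded at 180 s (1 discarded as warm-up) and 6 at
    60 s (2 discarded), i.e. about 9 + 6 minutes of tidal breathing per test;
    50 deterministic quantile compartments; N2O blood-gas partition
    coefficient 0.47.
    """

    n_compartments: int = 50
    lambda_b: float = 0.47
    vq_correlation: float = 0.0
    F0: float = 0.05
    A: float = 0.02
    periods: tuple[float, float] = (180.0, 60.0)
    n_periods: dict[float, float] = field(
        default_factory=lambda: {180.0: 3.0, 60.0: 6.0}
    )
    warmup_periods: dict[float, float] = field(
        default_factory=lambda: {180.0: 1.0, 60.0: 2.0}
    )

    def forcing(self, period_T: float, VT: float, RR: float) -> SineForcing:
        """Forcing for one period; the trace covers ``n_periods`` periods."""
        tau = 60.0 / RR
        # +1 breath so the recorded span covers n_periods even when the
        # breath duration does not divide the period
        n_breaths = math.ceil(self.n_periods[period_T] * period_T / tau) + 1
        return SineForcing(
            period_T=period_T,
            F0=self.F0,
            A=self.A,
            RR=RR,
            VT=VT,
            n_breaths=n_breaths,
        )
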