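import numpy as np
import pytest

from istct.cohort import ProtocolSpec
from istct.ist import recover_ist
from istct.logsd import MeasurementVector
from istct.lung import build_lung, simulate
from istct.settings import SimSettings


@pytest.fixture(scope="session")
def sim_settings() -> SimSettings:
    return SimSettings()


@pytest.fixture(scope="session")
def small_protocol() -> ProtocolSpec:
    """Two-animal cohort for fast structural tests."""
    return ProtocolSpec(n_animals=2, seed=7)


@pytest.fixture(scope="session")
def measure_ist(sim_settings):
    """Factory: run one paired two-period IST test on a synthetic lung.

    Returns a MeasurementVector; optional iid Gaussian expirate noise of sd
    ``noise * F0`` with the given seed.
    """

    def _measure(
        lsv,
        lsp,
        elv=900.0,
        vd=150.0,
        qp=3400.0,
        VT=300.0,
        RR=25.0,
        noise=0.0,
        seed=0,
    ) -> MeasurementVector:
        s = sim_settings
        lung = build_lung(elv, vd, qp, lsv, lsp, s.n_compartments, s.lambda_b)
        rng = np.random.default_rng(seed)
        y = {}
        for T in s.periods:
            tr = simulate(lung, s.forcing(T, VT, RR))
            if noise:
                tr.F_ET = tr.F_ET + rng.normal(0.0, noise * s.F0, len(tr))
            r = recover_ist(tr, s.lambda_b, warmup_periods=s.warmup_periods[T])
            y[T] = (r.ELV, r.Qp, r.Qp_mean)
        return MeasurementVector(
            y180=y[180.0],
            y60=y[60.0],
            elv_ref=y[180.0][0],
            qp_ref=y[180.0][1],
            vd=vd,
            VT=VT,
            RR=RR,
        )

    return _measure
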