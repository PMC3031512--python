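import numpy as np
import pytest

from translokin import fitting, pipeline, stimulus, synthetic
from translokin.model import TranslocationModel


@pytest.fixture
def model():
    """Reference model: tau = 16.6 min, steady-state y of 1 at 25 µM."""
    return TranslocationModel(tau=16.6, k=1.0 / 25.0)


@pytest.fixture
def cs_profile():
    return stimulus.make_continuous(25.0, 60.0)


def rk4_oracle(model, profile, sample_times, h=0.01):
    """Independent fine-step RK4 integration of tau*dy/dt + y = K*C(t).

    Integrates each constant-concentration interval separately with a fixed
    step, never using the closed-form exponential update, and interpolates
    to the sample times. Used only as a test oracle.
    """
    sample_times = np.asarray(sample_times, dtype=float)
    dense_t = [0.0]
    dense_y = [0.0]
    y = 0.0
    for i, c in enumerate(profile.levels):
        t0, t1 = profile.breakpoints[i], profile.breakpoints[i + 1]
        drive = model.k * c
        n = max(1, int(np.ceil((t1 - t0) / h)))
        step = (t1 - t0) / n

        def f(yv):
            return (drive - yv) / model.tau

        for _ in range(n):
            k1 = f(y)
            k2 = f(y + step * k1 / 2)
            k3 = f(y + step * k2 / 2)
            k4 = f(y + step * k3)
            y = y + step * (k1 + 2 * k2 + 2 * k3 + k4) / 6
            dense_t.append(dense_t[-1] + step)
            dense_y.append(y)
    return np.interp(sample_times, dense_t, dense_y)


@pytest.fixture(scope="session")
def recovery_taus():
    """Median-recovery experiment at the study conditions.

    200 seeded cohorts of 30 cells (3 explants) generated at tau = 16.6 min
    with 5% measurement noise, 20% cell-to-cell CV and 10-min sampling over
    120 min; each cohort pooled and refit by the two-step gain/log-linear
    procedure.
    """
    schedule = stimulus.RegionSchedule({"CS": stimulus.make_continuous(25.0, 120.0)})
    taus = []
    for seed in range(200):
        traces, _ = synthetic.generate_traces(
            synthetic.GeneratorConfig(seed=seed), schedule
        )
        mean = pipeline.pooled_mean_trace(traces)
        k_hat = fitting.estimate_gain(mean, 25.0)
        taus.append(fitting.fit_tau_loglinear(mean, k_hat, 25.0).tau_hat)
    return np.asarray(taus)
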