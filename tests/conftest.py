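import numpy as np
import pytest


def poisson_step_trials(rng, n_trials, base_hz=5.0, high_hz=50.0, onset_ms=50.0,
                        span=(-200.0, 400.0)):
    """Homogeneous-then-step Poisson trials (times in ms)."""
    out = []
    for _ in range(n_trials):
        pre = rng.uniform(span[0], onset_ms,
                          rng.poisson(base_hz * (onset_ms - span[0]) / 1000.0))
        post = rng.uniform(onset_ms, span[1],
                           rng.poisson(high_hz * (span[1] - onset_ms) / 1000.0))
        out.append(np.sort(np.r_[pre, post]))
    return out


@pytest.fixture(scope="session")
def trimodal_ptd_sample():
    rng = np.random.default_rng(11)
    return np.r_[rng.normal(0.20, 0.03, 100),
                 rng.normal(0.35, 0.03, 100),
                 rng.normal(0.55, 0.03, 100)]


@pytest.fixture(scope="session")
def small_population():
    from v4attn import synth

    pop = synth.PopulationConfig(n_units=30)
    units = synth.make_population(pop, seed=101)
    trials = synth.simulate_trials(
        units, synth.TrialConfig(n_trials_per_contrast_per_condition=20), seed=102)
    return units, trials
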