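"""CRF fitting, attentional modulation indices, and the contrast dependence
index."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from v4attn import synth
from v4attn.crf import (
    CRFParams,
    aggregate_by_group,
    ami_curve,
    ami_of_values,
    ami_params,
    analyze_unit,
    compute_cdi,
    fit_crf,
    fit_crf_grid,
    hyperbolic_ratio,
    screen_visual_responsiveness,
    spike_counts_to_rates,
)

CONTRASTS = np.geomspace(2.5, 80.0, 6)


def test_params_validation():
    with pytest.raises(ValueError):
        CRFParams(-1, 20, 2, 5)
    with pytest.raises(ValueError):
        CRFParams(50, 0, 2, 5)
    with pytest.raises(ValueError):
        CRFParams(50, 120, 2, 5)
    with pytest.raises(ValueError):
        CRFParams(50, 20, -2, 5)


def test_fit_recovers_noiseless_parameters():
    true = CRFParams(50, 20, 2, 5)
    fit, sse = fit_crf(CONTRASTS, true.rate(CONTRASTS))
    for a, b in zip(fit.as_array(), true.as_array()):
        assert abs(a - b) / b < 1e-4
    assert sse < 1e-8


def test_fit_constant_rates_degenerates_to_baseline():
    fit, _ = fit_crf(CONTRASTS, np.full(6, 12.0))
    assert fit.rate(CONTRASTS) == pytest.approx(np.full(6, 12.0), abs=1e-3)
    assert fit.r_max == pytest.approx(0.0, abs=1e-3)


def test_fit_requires_five_levels():
    with pytest.raises(ValueError):
        fit_crf([5, 10, 20, 40], [1.0, 2.0, 3.0, 4.0])


def test_fitted_curve_nondecreasing():
    rng = np.random.default_rng(0)
    grid = np.linspace(0, 100, 200)
    for _ in range(10):
        y = CRFParams(40, 15, 2, 4).rate(CONTRASTS) + rng.normal(0, 4, 6)
        fit, _ = fit_crf(CONTRASTS, y)
        assert np.all(np.diff(fit.rate(grid)) >= -1e-9)


def test_fit_beats_grid_search_oracle_under_noise():
    rng = np.random.default_rng(1)
    for _ in range(20):
        true = CRFParams(rng.uniform(20, 60), rng.uniform(8, 40),
                         rng.uniform(1, 3), rng.uniform(2, 8))
        y = true.rate(CONTRASTS) + rng.normal(0, 3, 6)
        _, sse_fit = fit_crf(CONTRASTS, y)
        _, sse_grid = fit_crf_grid(CONTRASTS, y)
        assert sse_fit <= sse_grid + 1e-9


# ---------------------------------------------------------------------------
# AMI / CDI


def test_ami_identity_and_closed_form():
    base = CRFParams(50, 20, 2, 5)
    assert np.allclose(ami_curve(base, base, CONTRASTS), 0.0)
    scaled = CRFParams(50 * 1.15, 20, 2, 5 * 1.15)
    ami = ami_curve(scaled, base, CONTRASTS)
    assert np.allclose(ami, 0.15 / 2.15)
    assert np.allclose(ami, 0.06977, atol=1e-5)


def test_ami_antisymmetric_under_condition_swap():
    a = CRFParams(55, 15, 2.2, 6)
    b = CRFParams(45, 22, 1.8, 4)
    assert np.allclose(ami_curve(a, b, CONTRASTS), -ami_curve(b, a, CONTRASTS))


def test_contrast_gain_gives_decreasing_ami():
    base = CRFParams(50, 20, 2, 0.0)
    shifted = CRFParams(50, 10, 2, 0.0)  # R_in(c) = R_away(2c)
    dense = np.geomspace(1, 100, 80)
    ami = ami_curve(shifted, base, dense)
    assert np.all(np.diff(ami) < 0)


def test_ami_params_closed_form():
    base = CRFParams(50, 20, 2, 5)
    assert all(v == 0 for v in ami_params(base, base).values())
    boosted = CRFParams(50 * 1.15, 20, 2, 5)
    out = ami_params(boosted, base)
    assert out["r_max"] == pytest.approx(0.0698, abs=1e-4)
    assert out["c50"] == out["n"] == out["m"] == 0.0


def test_cdi_arithmetic_and_flags():
    contrasts = np.array([5.0, 10.0, 40.0, 80.0])
    ami = np.array([0.2, 0.2, 0.1, 0.1])
    cdi, valid = compute_cdi(ami, contrasts, c50_away=20.0)
    assert valid and cdi == pytest.approx((0.2 - 0.1) / 0.15)
    # constant AMI -> CDI exactly 0 (pure response gain)
    cdi0, valid0 = compute_cdi(np.full(4, 0.2), contrasts, 20.0)
    assert valid0 and abs(cdi0) < 1e-12
    # threshold boundary counts as low
    cdi_b, _ = compute_cdi(ami, contrasts, c50_away=10.0)
    assert cdi_b == pytest.approx((0.2 - 0.1) / 0.15)
    # one-sided split flagged
    assert compute_cdi(ami, contrasts, 100.0)[1] is False
    # unstable denominator flagged
    assert compute_cdi(np.array([0.1, -0.1, 0.1, -0.1]), contrasts, 20.0)[1] is False


def test_cdi_invariant_under_positive_scaling_of_ami():
    contrasts = np.array([5.0, 10.0, 40.0, 80.0])
    ami = np.array([0.25, 0.18, 0.1, 0.05])
    c1, _ = compute_cdi(ami, contrasts, 20.0)
    c2, _ = compute_cdi(3.0 * ami, contrasts, 20.0)
    assert c1 == pytest.approx(c2)


@given(g=st.floats(0.5, 3.0))
@settings(max_examples=30, deadline=None)
def test_pure_response_gain_law_property(g):
    """R_in = g*R_away  =>  AMI = (g-1)/(g+1) at every contrast and CDI = 0."""
    base = CRFParams(40, 18, 2, 6)
    gained = CRFParams(40 * g, 18, 2, 6 * g)
    ami = ami_curve(gained, base, CONTRASTS)
    assert np.allclose(ami, (g - 1) / (g + 1), atol=1e-12)
    if abs(g - 1) > 0.05:
        cdi, valid = compute_cdi(ami, CONTRASTS, base.c50)
        assert valid and abs(cdi) < 1e-9


# ---------------------------------------------------------------------------
# trial-level


def _uniform_trial(n_spikes, lo, hi, rng):
    return np.sort(rng.uniform(lo, hi, n_spikes))


def test_spike_counts_window_arithmetic_and_boundaries(small_population):
    from v4attn.synth import TrialSet

    # 10 spikes uniformly inside [60, 260) per trial -> 50 spikes/s
    rng = np.random.default_rng(0)
    spikes = [{"attend_in": [[_uniform_trial(10, 60.0, 260.0, rng) for _ in range(5)]],
               "attend_away": [[np.array([60.0]), np.array([260.0]),
                                np.array([59.999]), np.array([259.999]),
                                np.array([])]]}]
    ts = TrialSet(contrasts=np.array([40.0]), conditions=("attend_in", "attend_away"),
                  trial_span=(-200.0, 400.0), stimulus_window=(0.0, 400.0),
                  spikes=spikes)
    tbl = spike_counts_to_rates(ts, 0, "attend_in")
    assert tbl["mean_rate"].iloc[0] == pytest.approx(50.0)
    tbl2 = spike_counts_to_rates(ts, 0, "attend_away")
    # spike at exactly 60 ms included, at exactly 260 ms excluded
    assert tbl2["mean_rate"].iloc[0] == pytest.approx((1 + 0 + 0 + 1 + 0) / 5 / 0.2)


def test_screen_responsiveness_null_and_power():
    from v4attn.synth import TrialSet

    rng = np.random.default_rng(2)

    def make_ts(base_hz, evoked_hz, n_trials=50):
        def trial():
            pre = _uniform_trial(rng.poisson(base_hz * 0.2), -200.0, 0.0, rng)
            post = _uniform_trial(rng.poisson(evoked_hz * 0.4), 0.0, 400.0, rng)
            return np.sort(np.r_[pre, post])
        spikes = [{c: [[trial() for _ in range(n_trials)]]
                   for c in ("attend_in", "attend_away")}]
        return TrialSet(np.array([80.0]), ("attend_in", "attend_away"),
                        (-200.0, 400.0), (0.0, 400.0), spikes)

    null_hits = sum(screen_visual_responsiveness(make_ts(10.0, 10.0), 0)
                    for _ in range(100))
    assert null_hits <= 12  # ~5% nominal
    power_hits = sum(screen_visual_responsiveness(make_ts(10.0, 30.0), 0)
                     for _ in range(50))
    assert power_hits >= 49
    zero = make_ts(0.0, 0.0)
    assert screen_visual_responsiveness(zero, 0) is False


def test_analyze_unit_recovers_injected_gain(small_population):
    units, trials = small_population
    i = next(idx for idx, u in enumerate(units) if u.cls == "narrow")
    prof = analyze_unit(trials, i)
    # narrow units carry pure response gain 1.10 -> mean AMI near 0.0476
    assert 0.0 < prof.mean_ami < 0.12
    assert prof.crf_in is not None and prof.crf_away is not None


def test_aggregate_by_group_identity_and_permutation(small_population):
    units, trials = small_population
    profs = [analyze_unit(trials, i) for i in range(12)]
    groups = ["a"] * 6 + ["b"] * 6
    out1 = aggregate_by_group(profs, groups, n_boot=500, seed=0)
    perm = np.random.default_rng(0).permutation(12)
    out2 = aggregate_by_group([profs[i] for i in perm], [groups[i] for i in perm],
                              n_boot=500, seed=0)
    for g in out1:
        assert out1[g]["mean_cdi"] == pytest.approx(out2[g]["mean_cdi"], nan_ok=True)
        assert np.allclose(out1[g]["mean_ami_curve"], out2[g]["mean_ami_curve"])


def test_aggregate_identical_units_zero_width_ci():
    from v4attn.crf import AMIProfile

    c = np.geomspace(2.5, 80, 6)
    prof = AMIProfile(contrasts=c, ami_by_contrast=np.full(6, 0.1),
                      ami_params={}, mean_ami=0.1, cdi=0.5, cdi_valid=True)
    out = aggregate_by_group([prof] * 5, ["g"] * 5, n_boot=500, seed=0)
    lo, hi = out["g"]["cdi_ci"]
    assert lo == pytest.approx(0.5) and hi == pytest.approx(0.5)


def test_ami_of_values_masks_zero_denominator():
    out = ami_of_values(np.array([1.0, 0.0]), np.array([1.0, 0.0]))
    assert out[0] == 0.0 and np.isnan(out[1])


def test_hyperbolic_ratio_zero_contrast_is_baseline():
    assert hyperbolic_ratio(0.0, 50, 20, 2, 5) == pytest.approx(5.0)
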