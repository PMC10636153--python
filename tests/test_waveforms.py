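"""Waveform features, meta-clustering, model selection and the dip test."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.cluster import KMeans

from v4attn.synth import make_waveform
from v4attn.waveforms import (
    classify_units,
    dip_statistic,
    dip_test,
    information_criteria,
    kneedle_elbow,
    match_labels,
    measure_ptd,
    meta_kmeans,
    normalize_waveforms,
    pca_crosscheck,
)

FS = 30_000.0


# ---------------------------------------------------------------------------
# peak-to-trough duration


@pytest.mark.parametrize("ptd_true", [0.20, 0.35, 0.40, 0.55])
def test_ptd_measured_matches_construction(ptd_true):
    _, v = make_waveform(ptd_true, fs=FS)
    half_step = 0.5 * 1000.0 / FS / 10
    assert abs(measure_ptd(v, FS) - ptd_true) < half_step


def test_ptd_invariant_under_scaling_and_offset():
    _, v = make_waveform(0.40, fs=FS)
    base = measure_ptd(v, FS)
    assert measure_ptd(10.0 * v, FS) == pytest.approx(base)
    assert measure_ptd(v + 3.7, FS) == pytest.approx(base)


@given(scale=st.floats(0.1, 50), offset=st.floats(-5, 5))
@settings(max_examples=25, deadline=None)
def test_ptd_affine_invariance_property(scale, offset):
    _, v = make_waveform(0.35, fs=FS)
    assert measure_ptd(scale * v + offset, FS) == pytest.approx(measure_ptd(v, FS))


def test_ptd_rejects_non_biphasic_shapes():
    _, v = make_waveform(0.40, fs=FS)
    with pytest.raises(ValueError, match="biphasic"):
        measure_ptd(-v, FS)  # inverted: peak precedes trough
    with pytest.raises(ValueError, match="biphasic"):
        measure_ptd(np.linspace(0.0, 1.0, 48), FS)  # monotone
    with pytest.raises(ValueError, match="biphasic"):
        measure_ptd(np.ones(48), FS)  # constant


def test_ptd_noisy_templates_vs_parabolic_oracle():
    """Spline-based extrema vs an independent parabolic-interpolation extremum
    finder on averaged noisy templates."""

    def parabolic_ptd(v, fs):
        def refine(idx, sign):
            y0, y1, y2 = sign * v[idx - 1], sign * v[idx], sign * v[idx + 1]
            denom = y0 - 2 * y1 + y2
            shift = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
            return idx + shift
        i_min = int(np.argmin(v))
        i_max = i_min + int(np.argmax(v[i_min:]))
        return (refine(i_max, -1.0) - refine(i_min, 1.0)) / fs * 1000.0

    rng = np.random.default_rng(3)
    deltas = []
    for _ in range(100):
        reps = [make_waveform(0.40, fs=FS, noise_sd=0.05,
                              seed=int(rng.integers(1 << 30)))[1] for _ in range(20)]
        avg = np.mean(reps, axis=0)
        deltas.append(abs(measure_ptd(avg, FS) - parabolic_ptd(avg, FS)))
    assert np.median(deltas) < 0.01


# ---------------------------------------------------------------------------
# meta-k-means


def test_meta_kmeans_separable_point_masses():
    x = np.r_[np.full(20, 0.2), np.full(20, 0.35), np.full(20, 0.55)]
    sol = meta_kmeans(x, k=3, n_restarts=50, seed=0)
    truth = np.r_[np.zeros(20), np.ones(20), np.full(20, 2)].astype(int)
    assert match_labels(truth, sol.labels) == 1.0
    assert set(np.unique(sol.consensus)) <= {0.0, 1.0}


def test_meta_kmeans_k1_and_errors():
    x = np.arange(10.0)
    sol = meta_kmeans(x, k=1, n_restarts=5, seed=0)
    assert np.all(sol.labels == 0)
    assert np.all(sol.consensus == 1.0)
    with pytest.raises(ValueError):
        meta_kmeans(np.arange(3.0), k=5, n_restarts=5, seed=0)
    with pytest.raises(ValueError):
        meta_kmeans(np.ones(10), k=2, n_restarts=5, seed=0)


def test_meta_kmeans_single_restart_equals_plain_kmeans():
    rng = np.random.default_rng(4)
    x = rng.normal(size=40)
    sol = meta_kmeans(x, k=3, n_restarts=1, seed=9)
    seed = int(np.random.SeedSequence(9).generate_state(1)[0] % (2**31 - 1))
    km = KMeans(n_clusters=3, n_init=1, init="random", random_state=seed)
    ref = km.fit_predict(x[:, None])
    assert match_labels(ref, sol.labels) == 1.0


def test_meta_kmeans_deterministic_and_recovers_gaussian_mixture():
    rng = np.random.default_rng(5)
    x = np.r_[rng.normal(0.2, 0.03, 80), rng.normal(0.35, 0.03, 80),
              rng.normal(0.55, 0.03, 80)]
    truth = np.repeat([0, 1, 2], 80)
    sol1 = meta_kmeans(x, k=3, n_restarts=100, seed=1)
    sol2 = meta_kmeans(x, k=3, n_restarts=100, seed=1)
    assert np.array_equal(sol1.labels, sol2.labels)
    assert np.allclose(sol1.consensus, sol2.consensus)
    assert match_labels(truth, sol1.labels) >= 0.95


# ---------------------------------------------------------------------------
# information criteria + kneedle


def test_information_criteria_select_three_clusters_on_average():
    rng = np.random.default_rng(6)
    wins = 0
    for _ in range(20):
        x = np.r_[rng.normal(0.2, 0.02, 60), rng.normal(0.35, 0.02, 60),
                  rng.normal(0.55, 0.02, 60)]
        aics = {}
        for k in (2, 3, 4):
            sol = meta_kmeans(x, k=k, n_restarts=20, seed=7)
            aics[k], _ = information_criteria(x, sol.labels, k)
        wins += aics[3] < aics[2] and aics[3] < aics[4]
    assert wins >= 15


def test_bic_prefers_one_cluster_for_single_gaussian():
    rng = np.random.default_rng(7)
    wins = 0
    for _ in range(50):
        x = rng.normal(size=100)
        bic1 = information_criteria(x, np.zeros(100, int), 1)[1]
        sol = meta_kmeans(x, k=2, n_restarts=10, seed=3)
        bic2 = information_criteria(x, sol.labels, 2)[1]
        wins += bic1 < bic2
    assert wins >= 45


def test_information_criteria_variance_floor_on_degenerate_data():
    x = np.ones(20)
    with pytest.warns(UserWarning, match="floored"):
        aic, bic = information_criteria(x, np.zeros(20, int), 1)
    assert np.isfinite(aic) and np.isfinite(bic)


def test_kneedle_constructed_elbow_and_sentinels():
    y = [10.0, 4.0, 1.0, 0.9, 0.85, 0.84]
    assert kneedle_elbow(range(1, 7), y) == 3
    assert kneedle_elbow(range(1, 7), np.linspace(10, 0, 6)) is None
    assert kneedle_elbow(range(1, 7), np.ones(6)) is None
    with pytest.raises(ValueError):
        kneedle_elbow([1, 2], [3.0, 1.0])


# ---------------------------------------------------------------------------
# Hartigan's dip


def _convex_env_vals(x, y):
    hull = []
    for xi, yi in zip(x, y):
        hull.append((xi, yi))
        while len(hull) >= 3:
            (x1, y1), (x2, y2), (x3, y3) = hull[-3:]
            if (y2 - y1) * (x3 - x1) >= (y3 - y1) * (x2 - x1):
                del hull[-2]
            else:
                break
    hx = np.array([p[0] for p in hull])
    hy = np.array([p[1] for p in hull])
    return np.interp(x, hx, hy)


def _feasible_side(x, lo, hi):
    """Does a convex nondecreasing function fit within the [lo, hi] band?"""
    if len(x) == 0:
        return True
    xs, inv = np.unique(np.asarray(x), return_inverse=True)
    hi_c = np.full(xs.size, np.inf)
    lo_c = np.full(xs.size, -np.inf)
    for i, g in enumerate(inv):
        hi_c[g] = min(hi_c[g], hi[i])
        lo_c[g] = max(lo_c[g], lo[i])
    return np.all(_convex_env_vals(xs, hi_c) >= lo_c - 1e-12)


def _dip_bruteforce(sample):
    """Definitional dip: binary search on d, feasibility of a convex/concave
    CDF pair over every split of the sorted sample."""
    x = np.sort(np.asarray(sample, float))
    n = x.size

    def feasible(d):
        for j in range(n + 1):
            i_l = np.arange(1, j + 1)
            i_r = np.arange(j + 1, n + 1)
            left = _feasible_side(x[:j], i_l / n - d, (i_l - 1) / n + d)
            right = _feasible_side(-x[j:][::-1], (1 - ((i_r - 1) / n + d))[::-1],
                                   (1 - (i_r / n - d))[::-1])
            if left and right:
                return True
        return False

    lo_d, hi_d = 0.0, 0.5
    for _ in range(45):
        mid = (lo_d + hi_d) / 2
        if feasible(mid):
            hi_d = mid
        else:
            lo_d = mid
    return hi_d


def test_dip_matches_bruteforce_oracle_on_small_samples():
    rng = np.random.default_rng(42)
    for trial in range(30):
        n = int(rng.integers(4, 25))
        if trial % 3 == 0:
            s = rng.random(n)
        elif trial % 3 == 1:
            s = np.round(rng.random(n) * 4) / 4  # heavy ties
        else:
            s = np.r_[rng.normal(0, 0.05, n // 2), rng.normal(1, 0.05, n - n // 2)]
        assert dip_statistic(s) == pytest.approx(_dip_bruteforce(s), abs=1e-9)


def test_dip_two_point_masses_approaches_quarter():
    x = np.r_[np.zeros(500), np.ones(500)]
    assert abs(dip_statistic(x) - 0.25) < 0.01


def test_dip_range_and_degenerate_cases():
    rng = np.random.default_rng(1)
    for n in (10, 100, 500):
        d = dip_statistic(rng.random(n))
        assert 0.0 <= d <= 0.25
    assert dip_statistic(np.ones(50)) == 0.0
    assert dip_test(np.ones(50)) == (0.0, 1.0)
    with pytest.raises(ValueError):
        dip_test(np.arange(5.0))


@given(st.integers(0, 10_000))
@settings(max_examples=30, deadline=None)
def test_dip_bounds_property(seed):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=int(rng.integers(10, 200)))
    assert 0.0 < dip_statistic(x) <= 0.25


def test_dip_null_calibration_uniform():
    hits = 0
    for s in range(30):
        rng = np.random.default_rng(s)
        _, p = dip_test(rng.random(500), n_boot=500, seed=77)
        hits += p > 0.05
    assert hits >= 27


# ---------------------------------------------------------------------------
# PCA cross-check


def test_pca_crosscheck_exact_two_component_data():
    rng = np.random.default_rng(8)
    comp = rng.normal(size=(2, 40))
    scores = np.vstack([rng.normal([5, 0], 0.1, size=(30, 2)),
                        rng.normal([0, 5], 0.1, size=(30, 2)),
                        rng.normal([-5, -5], 0.1, size=(30, 2))])
    W = scores @ comp
    labels = np.repeat([0, 1, 2], 30)
    _, agreement, ev = pca_crosscheck(W, labels, k=3, seed=0)
    assert agreement == 1.0
    assert ev.sum() > 0.99


def test_pca_crosscheck_random_labels_near_chance():
    rng = np.random.default_rng(9)
    comp = rng.normal(size=(2, 40))
    scores = np.vstack([rng.normal([5, 0], 0.1, size=(100, 2)),
                        rng.normal([0, 5], 0.1, size=(100, 2)),
                        rng.normal([-5, -5], 0.1, size=(100, 2))])
    W = scores @ comp
    random_labels = rng.integers(0, 3, 300)
    _, agreement, _ = pca_crosscheck(W, random_labels, k=3, seed=0)
    assert 0.28 <= agreement <= 0.45


def test_classification_pipeline_on_synthetic_population():
    from v4attn import synth

    units = synth.make_population(synth.PopulationConfig(n_units=200), seed=21)
    wf = np.vstack([make_waveform(u.ptd_true, fs=FS, noise_sd=0.02,
                                  seed=u.unit_id)[1] for u in units])
    res = classify_units(wf, fs=FS, n_restarts=100, seed=5)
    assert res["k_aic"] == 3
    truth = np.array([synth.CLASSES.index(u.cls) for u in units])
    assert match_labels(truth, res["labels"]) >= 0.9
    norm, _ = normalize_waveforms(wf, FS)
    _, agreement, _ = pca_crosscheck(norm, res["labels"], k=3, seed=0)
    assert agreement >= 0.8
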