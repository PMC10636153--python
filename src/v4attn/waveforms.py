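"""Spike-waveform features and unit classification.

Units are classified into Narrow / Medium / Broad spiking classes from the
peak-to-trough duration (PTD) of their mean action-potential waveform:

* PTD is measured on a cubic-spline-upsampled trace as the time from the
  global trough to the subsequent global peak.
* Classes come from a meta-clustering analysis: k-means is restarted many
  times with random initialization, a consensus (co-assignment) matrix is
  accumulated, and the final partition is an average-linkage agglomerative cut
  of the consensus distances.
* The number of clusters is selected by the kneedle elbow of AIC/BIC curves
  computed from a hard-assignment Gaussian mixture likelihood.
* Multimodality of the PTD distribution is assessed with Hartigan's dip test
  (bootstrap p-value against a uniform null).
* A PCA cross-check clusters the full normalized waveforms in the space of the
  first two principal components and reports agreement with the PTD classes.
"""

from __future__ import annotations

import functools
import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.interpolate import CubicSpline
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

__all__ = [
    "ClusterSolution",
    "measure_ptd",
    "normalize_waveforms",
    "meta_kmeans",
    "information_criteria",
    "kneedle_elbow",
    "dip_statistic",
    "dip_test",
    "match_labels",
    "pca_crosscheck",
    "classify_units",
    "CLASS_NAMES",
]

CLASS_NAMES = ("narrow", "medium", "broad")


@dataclass
class ClusterSolution:
    k: int
    labels: np.ndarray
    centers: np.ndarray
    aic: float
    bic: float
    consensus: np.ndarray


# ---------------------------------------------------------------------------
# peak-to-trough duration


def measure_ptd(waveform, fs, upsample_factor=10):
    """Peak-to-trough duration (ms) of a biphasic trough-then-peak waveform.

    The trace is upsampled with a cubic spline; PTD is the time from the
    global minimum (trough) to the subsequent global maximum (peak).  Raises
    ``ValueError`` for non-biphasic shapes (constant, monotone, or inverted
    polarity where the peak precedes the trough).
    """
    v = np.asarray(waveform, float)
    if v.ndim != 1 or v.size < 8:
        raise ValueError("waveform must be 1-D with at least 8 samples")
    if np.ptp(v) == 0:
        raise ValueError("no biphasic shape: constant waveform")
    t = np.arange(v.size) / fs * 1000.0  # ms
    fine_t = np.linspace(t[0], t[-1], v.size * int(upsample_factor))
    fine_v = CubicSpline(t, v)(fine_t)
    i_min = int(np.argmin(fine_v))
    i_max = int(np.argmax(fine_v))
    if i_max <= i_min:
        raise ValueError("no biphasic shape: peak precedes trough")
    if i_min in (0, fine_v.size - 1) or i_max == fine_v.size - 1:
        raise ValueError("no biphasic shape: extremum at trace boundary")
    return float(fine_t[i_max] - fine_t[i_min])


def normalize_waveforms(waveforms, fs, upsample_factor=4):
    """Align traces to a common trough index and normalize peak height to 1.

    Returns (matrix, fine_fs): spline-upsampled, trough-aligned, amplitude-
    normalized waveforms stacked as rows, cropped to the span common to all
    units.
    """
    waveforms = np.asarray(waveforms, float)
    n, T = waveforms.shape
    fine_T = T * int(upsample_factor)
    t = np.arange(T)
    ft = np.linspace(0, T - 1, fine_T)
    fine = np.vstack([CubicSpline(t, w)(ft) for w in waveforms])
    troughs = fine.argmin(axis=1)
    left = int(troughs.min())
    right = int((fine_T - troughs).min())
    out = np.empty((n, left + right))
    for i in range(n):
        seg = fine[i, troughs[i] - left: troughs[i] + right]
        peak = np.abs(seg).max()
        out[i] = seg / peak if peak > 0 else seg
    return out, fs * upsample_factor * (fine_T - 1) / (T - 1) / upsample_factor


# ---------------------------------------------------------------------------
# meta-clustering


def meta_kmeans(features, k, n_restarts=500, seed=0):
    """Consensus k-means: many random-init restarts, co-assignment matrix,
    average-linkage cut of the consensus distances at ``k`` clusters.
    """
    X = np.asarray(features, float)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds the number of units ({n})")
    if np.unique(X, axis=0).shape[0] < k:
        raise ValueError("fewer distinct feature values than clusters")
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")

    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(n_restarts)
    consensus = np.zeros((n, n))
    for s in child_seeds:
        km = KMeans(n_clusters=k, n_init=1, init="random",
                    random_state=int(s % (2**31 - 1)))
        lab = km.fit_predict(X)
        consensus += lab[:, None] == lab[None, :]
    consensus /= n_restarts
    np.fill_diagonal(consensus, 1.0)

    if k == 1:
        labels = np.zeros(n, dtype=int)
    else:
        dist = squareform(1.0 - consensus, checks=False)
        labels = fcluster(linkage(dist, method="average"), k, criterion="maxclust") - 1
    centers = np.vstack([X[labels == c].mean(axis=0) for c in range(labels.max() + 1)])
    aic, bic = information_criteria(X, labels, int(labels.max() + 1))
    return ClusterSolution(k=k, labels=labels, centers=centers,
                           aic=aic, bic=bic, consensus=consensus)


def information_criteria(features, labels, k, var_floor=1e-6):
    """AIC/BIC of a hard-assignment (diagonal) Gaussian mixture.

    Log-likelihood uses per-cluster mean and variance per feature dimension
    plus mixing weights; parameter count p = k*(2d) + (k-1), i.e. 3k-1 in 1-D.
    Singleton or degenerate clusters get their variance floored.
    """
    X = np.asarray(features, float)
    if X.ndim == 1:
        X = X[:, None]
    n, d = X.shape
    labels = np.asarray(labels)
    lnL = 0.0
    for c in range(k):
        xc = X[labels == c]
        nc = xc.shape[0]
        if nc == 0:
            continue
        mu = xc.mean(axis=0)
        var = xc.var(axis=0)
        if np.any(var < var_floor):
            warnings.warn(f"cluster {c}: variance floored at {var_floor}")
            var = np.maximum(var, var_floor)
        w = nc / n
        ll = -0.5 * np.sum(np.log(2 * np.pi * var)[None, :] + (xc - mu) ** 2 / var[None, :])
        lnL += ll + nc * np.log(w)
    p = k * 2 * d + (k - 1)
    aic = 2 * p - 2 * lnL
    bic = p * np.log(n) - 2 * lnL
    return float(aic), float(bic)


def kneedle_elbow(k_values, criterion_values, tol=1e-12):
    """Elbow of a decreasing criterion curve by the kneedle difference curve.

    Both axes are min-max normalized; the difference curve is
    d_i = (1 - x_i) - y_i and the elbow is the k at its global maximum
    (smallest k on ties).  Returns ``None`` when the curve is linear (no
    elbow).
    """
    k_values = np.asarray(k_values, float)
    y = np.asarray(criterion_values, float)
    if k_values.size < 3:
        raise ValueError("need at least 3 points to locate an elbow")
    x_hat = (k_values - k_values.min()) / np.ptp(k_values)
    if np.ptp(y) == 0:
        return None
    y_hat = (y - y.min()) / np.ptp(y)
    diff = (1.0 - x_hat) - y_hat
    if diff.max() <= tol:
        return None
    return int(k_values[int(np.argmax(diff))])


# ---------------------------------------------------------------------------
# Hartigan's dip test


@njit(cache=True)
def _prefix_halfdev(x, h):
    """Max deviation of band centers h above their convex envelope, per prefix.

    Returns dev where dev[j] is max_{i<j} (h[i] - envelope_{0..j-1}(x[i])),
    the envelope being the greatest convex minorant of the points seen so far.
    """
    n = x.size
    dev = np.zeros(n + 1)
    hull = np.empty(n, np.int64)
    m = 0
    cur = 0.0
    for j in range(n):
        if m > 0 and x[j] == x[hull[m - 1]]:
            # tied abscissa: envelope keeps the earlier (lower) value
            d = h[j] - h[hull[m - 1]]
            if d > cur:
                cur = d
            dev[j + 1] = cur
            continue
        while m >= 2:
            a = hull[m - 2]
            b = hull[m - 1]
            if (h[b] - h[a]) * (x[j] - x[a]) >= (h[j] - h[a]) * (x[b] - x[a]):
                m -= 1
            else:
                break
        hull[m] = j
        m += 1
        if m >= 2:
            a = hull[m - 2]
            slope = (h[j] - h[a]) / (x[j] - x[a])
            for i in range(a + 1, j):
                d = h[i] - (h[a] + slope * (x[i] - x[a]))
                if d > cur:
                    cur = d
        dev[j + 1] = cur
    return dev


def dip_statistic(sample):
    """Hartigan's dip: sup-norm distance from the ECDF to the nearest
    unimodal CDF.

    Computed by splitting the sorted sample at every candidate mode position,
    measuring the minimal band inflation needed for a convex (left) /
    concave (right) CDF piece via greatest-convex-minorant deviations, and
    minimizing over splits.  Always in [0, 0.25]; 0 for constant samples.
    """
    x = np.sort(np.asarray(sample, float))
    n = x.size
    if n < 2 or x[0] == x[-1]:
        return 0.0
    h = (np.arange(1, n + 1) - 0.5) / n
    dev_l = _prefix_halfdev(x, h)
    dev_r = _prefix_halfdev(-x[::-1], (1.0 - h)[::-1])
    # split j: points 1..j convex side, j+1..n concave side
    best = np.minimum.reduce(np.maximum(dev_l, dev_r[::-1]))
    return float(0.5 / n + 0.5 * best)


@functools.lru_cache(maxsize=32)
def _dip_null_table(n, n_boot, seed):
    rng = np.random.default_rng(seed)
    return np.array([dip_statistic(rng.random(n)) for _ in range(n_boot)])


def dip_test(sample, n_boot=2000, seed=0):
    """Dip statistic and bootstrap p-value against a uniform(0,1) null.

    The null distribution depends only on the sample size; tables are cached
    per (n, n_boot, seed).
    """
    x = np.asarray(sample, float)
    if x.size < 10:
        raise ValueError("dip test needs n >= 10")
    stat = dip_statistic(x)
    if stat == 0.0:
        return 0.0, 1.0
    null = _dip_null_table(int(x.size), int(n_boot), int(seed))
    return stat, float(np.mean(null >= stat))


# ---------------------------------------------------------------------------
# PCA cross-check


def match_labels(labels_a, labels_b):
    """Best agreement fraction between two labelings (Hungarian matching)."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    ka, kb = a.max() + 1, b.max() + 1
    if ka != kb:
        raise ValueError(f"label sets have different k ({ka} vs {kb})")
    cont = np.zeros((ka, kb))
    for i, j in zip(a, b):
        cont[i, j] += 1
    rows, cols = linear_sum_assignment(-cont)
    return float(cont[rows, cols].sum() / a.size)


def pca_crosscheck(norm_waveforms, ptd_labels, k, seed=0, n_restarts=100):
    """Cluster full waveforms in the first-2-PC space; agreement with PTD labels.

    Returns (pc_labels, agreement_fraction, explained_variance_fractions).
    """
    W = np.asarray(norm_waveforms, float)
    pca = PCA(n_components=min(10, *W.shape), random_state=seed)
    scores = pca.fit_transform(W)
    sol = meta_kmeans(scores[:, :2], k=k, n_restarts=n_restarts, seed=seed)
    agreement = match_labels(np.asarray(ptd_labels), sol.labels)
    return sol.labels, agreement, pca.explained_variance_ratio_[:2].copy()


# ---------------------------------------------------------------------------
# high level


def classify_units(waveforms, fs, k_range=range(1, 7), n_restarts=500, seed=0,
                   upsample_factor=10):
    """Full classification of a population of mean waveforms.

    Measures PTD per unit, sweeps k with meta-k-means, selects k by the
    kneedle elbow of AIC (falling back to BIC), names clusters by ascending
    mean PTD (narrow < medium < broad for k=3), and runs the dip test.

    Returns a dict with keys ``ptd_ms, k_aic, k_bic, k, solution, labels,
    class_names, dip, dip_p, solutions``.
    """
    ptd = np.array([measure_ptd(w, fs, upsample_factor) for w in waveforms])
    sample_step_ms = 1000.0 / fs / upsample_factor
    ks = list(k_range)
    solutions = {}
    aics, bics = [], []
    for k in ks:
        sol = meta_kmeans(ptd, k, n_restarts=n_restarts, seed=seed + k)
        a, b = information_criteria(ptd, sol.labels, k, var_floor=sample_step_ms**2)
        sol.aic, sol.bic = a, b
        solutions[k] = sol
        aics.append(a)
        bics.append(b)
    k_aic = kneedle_elbow(ks, aics)
    k_bic = kneedle_elbow(ks, bics)
    k_sel = k_aic if k_aic is not None else (k_bic if k_bic is not None else ks[0])
    sol = solutions[k_sel]
    # rank clusters by mean PTD so label 0 is the narrowest
    order = np.argsort([ptd[sol.labels == c].mean() for c in range(k_sel)])
    remap = np.empty(k_sel, dtype=int)
    remap[order] = np.arange(k_sel)
    labels = remap[sol.labels]
    if k_sel == 3:
        names = [CLASS_NAMES[c] for c in labels]
    else:
        names = [f"cluster{c}" for c in labels]
    dip, dip_p = dip_test(ptd, seed=seed)
    return {
        "ptd_ms": ptd,
        "k_aic": k_aic,
        "k_bic": k_bic,
        "k": k_sel,
        "solution": sol,
        "labels": labels,
        "class_names": names,
        "aic": np.array(aics),
        "bic": np.array(bics),
        "dip": dip,
        "dip_p": dip_p,
        "solutions": solutions,
    }
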