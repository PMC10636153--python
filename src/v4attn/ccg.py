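"""Spike-time cross-correlograms between pooled spike trains.

Spike trains are binned at 1 ms within trials; the correlogram counts
coincidences of target spikes at each lag relative to reference spikes,
normalized by the geometric mean of the two pooled spike counts.  Stimulus-
locked covariation is removed with a predictor: the all-pairs shuffle
predictor (cross-trial PSTH product, default — the average of every possible
trial rotation), a one-rotation shift predictor, or an interval-jitter
predictor.  Summaries use the mean corrected value within a +/-25 ms window
around zero lag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["Correlogram", "pooled_ccg", "window_mean", "group_ccg_by_layer",
           "split_by_trials"]


@dataclass
class Correlogram:
    lags: np.ndarray           # ms, symmetric around 0, 1-ms bins
    value: np.ndarray          # normalized (and corrected, if requested)
    raw_counts: np.ndarray     # integer pair counts at each lag
    predictor: np.ndarray | None
    corrected: bool
    n_spikes_ref: int
    n_spikes_tgt: int
    flagged: bool = False


def split_by_trials(train_ms, trial_boundaries):
    """Split a flat spike-time array into per-trial arrays, relative to each
    trial's start."""
    t = np.sort(np.asarray(train_ms, float))
    return [t[(t >= t0) & (t < t1)] - t0 for t0, t1 in trial_boundaries]


def _bin_trials(trials, n_bins, bin_ms):
    out = np.zeros((len(trials), n_bins), np.int64)
    for i, t in enumerate(trials):
        idx = np.floor(np.asarray(t, float) / bin_ms).astype(int)
        idx = idx[(idx >= 0) & (idx < n_bins)]
        np.add.at(out[i], idx, 1)
    return out


def _xcorr(a, b, max_bins):
    """c[k] = sum_t a[t] * b[t + k] for k in [-max_bins, max_bins]."""
    full = np.correlate(b.astype(float), a.astype(float), mode="full")
    center = a.size - 1
    return full[center - max_bins: center + max_bins + 1]


def pooled_ccg(train_ref, train_tgt, trial_boundaries=None, max_lag=100.0,
               correction="shuffle", bin_ms=1.0, jitter_ms=25.0, n_jitter=10,
               seed=0):
    """Corrected cross-correlogram of two pooled spike trains.

    Parameters
    ----------
    train_ref, train_tgt : flat spike-time arrays (ms) or lists of per-trial
        arrays on a common per-trial time base.  Flat arrays require
        ``trial_boundaries`` (list of (t0, t1)).
    correction : "shuffle" (all-trial-pairs predictor, default), "shift"
        (one-trial rotation), "jitter" (mean of interval-jitter surrogates),
        or None for the raw correlogram.

    The value axis is coincidence counts per 1-ms lag bin divided by the
    geometric mean of the two pooled spike counts; the predictor is
    subtracted when a correction is requested.
    """
    if max_lag < 25.0:
        raise ValueError("max_lag must be >= 25 ms")
    if isinstance(train_ref, np.ndarray) or (len(train_ref) and np.isscalar(train_ref[0])):
        if trial_boundaries is None:
            raise ValueError("flat trains require trial_boundaries")
        ref_trials = split_by_trials(np.asarray(train_ref, float), trial_boundaries)
        tgt_trials = split_by_trials(np.asarray(train_tgt, float), trial_boundaries)
    else:
        ref_trials = [np.asarray(t, float) for t in train_ref]
        tgt_trials = [np.asarray(t, float) for t in train_tgt]
    if len(ref_trials) != len(tgt_trials):
        raise ValueError("reference and target must share the trial structure")

    max_bins = int(round(max_lag / bin_ms))
    lags = np.arange(-max_bins, max_bins + 1) * bin_ms
    n_ref = int(sum(t.size for t in ref_trials))
    n_tgt = int(sum(t.size for t in tgt_trials))
    if n_ref == 0 or n_tgt == 0:
        warnings.warn("empty spike train; returning zero correlogram")
        z = np.zeros(lags.size)
        return Correlogram(lags, z, z.astype(np.int64), None, False, n_ref, n_tgt,
                           flagged=True)

    t_max = max(max((t.max() for t in tr if t.size), default=0.0)
                for tr in (ref_trials, tgt_trials))
    n_bins = int(np.floor(t_max / bin_ms)) + 1
    A = _bin_trials(ref_trials, n_bins, bin_ms)
    B = _bin_trials(tgt_trials, n_bins, bin_ms)
    R = A.shape[0]

    raw = np.zeros(lags.size)
    for i in range(R):
        raw += _xcorr(A[i], B[i], max_bins)
    norm = np.sqrt(float(n_ref) * float(n_tgt))
    value = raw / norm

    predictor = None
    if correction == "shuffle":
        if R < 2:
            raise ValueError("shuffle predictor needs >= 2 trials")
        all_pairs = _xcorr(A.sum(axis=0), B.sum(axis=0), max_bins)
        predictor = (all_pairs - raw) / (R - 1) / norm
    elif correction == "shift":
        if R < 2:
            raise ValueError("shift predictor needs >= 2 trials")
        pred = np.zeros(lags.size)
        for i in range(R):
            pred += _xcorr(A[i], B[(i + 1) % R], max_bins)
        predictor = pred / norm
    elif correction == "jitter":
        rng = np.random.default_rng(seed)
        acc = np.zeros(lags.size)
        for _ in range(n_jitter):
            jit = []
            for t in tgt_trials:
                if t.size == 0:
                    jit.append(t)
                    continue
                bins = np.floor(t / jitter_ms)
                jit.append(np.sort((bins + rng.random(t.size)) * jitter_ms))
            Bj = _bin_trials(jit, n_bins, bin_ms)
            for i in range(R):
                acc += _xcorr(A[i], Bj[i], max_bins)
        predictor = acc / n_jitter / norm
    elif correction is not None:
        raise ValueError(f"unknown correction {correction!r}")

    corrected = predictor is not None
    if corrected:
        value = value - predictor
    return Correlogram(lags, value, raw.astype(np.int64), predictor, corrected,
                       n_ref, n_tgt)


def window_mean(correlogram: Correlogram, window_halfwidth=25.0):
    """Mean correlogram value over lags within +/-window_halfwidth ms."""
    if window_halfwidth > correlogram.lags.max():
        raise ValueError("window exceeds the correlogram lag range")
    sel = np.abs(correlogram.lags) <= window_halfwidth
    return float(correlogram.value[sel].mean())


def group_ccg_by_layer(sessions, pairs=(("broad", "narrow"), ("broad", "medium")),
                       max_lag=100.0, correction="shuffle", **kwargs):
    """Layer-wise class-pair correlograms, pooled within sessions and averaged
    across sessions.

    Parameters
    ----------
    sessions : list of dicts with keys ``trains`` (per-unit lists of per-trial
        spike arrays), ``cls`` (per-unit class names), ``layer`` (per-unit
        layer names).
    pairs : (reference class, target class) tuples; the reference defaults to
        the broad (putative excitatory) class, targets to narrow/medium
        (putative inhibitory) classes.

    Returns {layer: {pair: averaged Correlogram}}; layers missing a class in
    every session are skipped with a warning.
    """
    layers = sorted({l for s in sessions for l in s["layer"]})
    out = {}
    for layer in layers:
        out_layer = {}
        for ref_cls, tgt_cls in pairs:
            ccgs = []
            for sess in sessions:
                ref_units = [tr for tr, c, l in zip(sess["trains"], sess["cls"], sess["layer"])
                             if c == ref_cls and l == layer]
                tgt_units = [tr for tr, c, l in zip(sess["trains"], sess["cls"], sess["layer"])
                             if c == tgt_cls and l == layer]
                if not ref_units or not tgt_units:
                    continue
                n_trials = len(ref_units[0])
                pooled_ref = [np.sort(np.concatenate([u[t] for u in ref_units]))
                              for t in range(n_trials)]
                pooled_tgt = [np.sort(np.concatenate([u[t] for u in tgt_units]))
                              for t in range(n_trials)]
                ccgs.append(pooled_ccg(pooled_ref, pooled_tgt, max_lag=max_lag,
                                       correction=correction, **kwargs))
            if not ccgs:
                warnings.warn(f"layer {layer!r}: no session with classes "
                              f"{ref_cls}/{tgt_cls}; skipped")
                continue
            mean_value = np.mean([c.value for c in ccgs], axis=0)
            out_layer[(ref_cls, tgt_cls)] = Correlogram(
                lags=ccgs[0].lags, value=mean_value,
                raw_counts=np.sum([c.raw_counts for c in ccgs], axis=0),
                predictor=None, corrected=ccgs[0].corrected,
                n_spikes_ref=sum(c.n_spikes_ref for c in ccgs),
                n_spikes_tgt=sum(c.n_spikes_tgt for c in ccgs))
        if out_layer:
            out[layer] = out_layer
    return out
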