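"""Contrast-response-function fitting and attentional-modulation indices.

The contrast response function (CRF) of a visual neuron is modelled with the
four-parameter hyperbolic ratio (Naka–Rushton) form

    R(c) = m + r_max * c**n / (c**n + c50**n)

where ``r_max`` is the attainable maximum response above baseline, ``c50`` the
contrast at which the evoked response is half-maximal, ``n`` the nonlinearity
exponent, and ``m`` the baseline (spontaneous) rate.

The effect of spatial attention on a unit is summarized by the attentional
modulation index AMI(c) = (R_in(c) - R_away(c)) / (R_in(c) + R_away(c)),
evaluated per contrast and applied analogously to each fitted parameter, and by
the contrast dependence index (CDI): the difference between the mean AMI over
low contrasts (c <= c50 of the attend-away fit) and over high contrasts,
normalized by the mean AMI over all contrasts.  CDI = 0 indicates pure response
gain (contrast-independent scaling); CDI > 0 indicates stronger modulation at
low contrasts (contrast-gain-like).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "CRFParams",
    "AMIProfile",
    "hyperbolic_ratio",
    "fit_crf",
    "fit_crf_grid",
    "ami_of_values",
    "ami_curve",
    "ami_params",
    "compute_cdi",
    "spike_counts_to_rates",
    "screen_visual_responsiveness",
    "analyze_unit",
    "aggregate_by_group",
]

#: spike-count window (ms after stimulus onset), half-open [lo, hi)
COUNT_WINDOW = (60.0, 260.0)
#: pre-stimulus window used for baseline rate estimates (ms)
BASELINE_WINDOW = (-200.0, 0.0)

PARAM_NAMES = ("r_max", "c50", "n", "m")


@dataclass(frozen=True)
class CRFParams:
    """Parameters of a hyperbolic-ratio contrast response function."""

    r_max: float  # spikes/s, evoked range above baseline
    c50: float    # percent contrast of half-maximal evoked response
    n: float      # dimensionless exponent
    m: float      # spikes/s baseline

    def __post_init__(self) -> None:
        if self.r_max < 0 or self.m < 0:
            raise ValueError("r_max and m must be nonnegative")
        if not (0 < self.c50 <= 100):
            raise ValueError(f"c50 must lie in (0, 100], got {self.c50}")
        if self.n <= 0:
            raise ValueError("exponent n must be positive")

    def rate(self, contrast):
        """Evaluate R(c) at percent contrast ``contrast``."""
        return hyperbolic_ratio(contrast, self.r_max, self.c50, self.n, self.m)

    def as_array(self) -> np.ndarray:
        return np.array([self.r_max, self.c50, self.n, self.m], float)


@dataclass
class AMIProfile:
    """Per-unit attentional-modulation summary."""

    contrasts: np.ndarray
    ami_by_contrast: np.ndarray
    ami_params: dict[str, float]
    mean_ami: float
    cdi: float               # nan when flagged unstable
    cdi_valid: bool
    crf_in: CRFParams | None = None
    crf_away: CRFParams | None = None
    flags: list[str] = field(default_factory=list)


def hyperbolic_ratio(c, r_max, c50, n, m):
    """R(c) = m + r_max * c^n / (c^n + c50^n), vectorized over contrast."""
    c = np.asarray(c, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        cn = np.where(c > 0, np.power(c, n), 0.0)
    return m + r_max * cn / (cn + c50**n)


# ---------------------------------------------------------------------------
# fitting


def _sse(params, c, y):
    r_max, c50, n, m = params
    resid = hyperbolic_ratio(c, r_max, c50, n, m) - y
    return float(resid @ resid)


def fit_crf(
    contrasts,
    mean_rates,
    c50_starts=(5.0, 10.0, 20.0, 40.0, 80.0),
    n_starts=(1.0, 2.0, 4.0),
):
    """Fit the hyperbolic-ratio CRF to per-contrast mean rates by bounded OLS.

    Multi-start nonlinear least squares over a fixed initialization grid of
    (c50, n); returns the converged start with the lowest sum of squared
    errors.

    Returns
    -------
    (CRFParams, sse) : best-fitting parameters and their SSE.
    """
    c = np.asarray(contrasts, float)
    y = np.asarray(mean_rates, float)
    if c.ndim != 1 or c.shape != y.shape:
        raise ValueError("contrasts and mean_rates must be 1-D of equal length")
    if c.size < 5:
        raise ValueError("need at least 5 contrast levels for a 4-parameter fit")

    ymax = float(np.max(y))
    rng_y = ymax - float(np.min(y))
    # bounds: r_max in [0, 5*max rate], c50 in (0.5, 100], n in [0.3, 6], m in [0, max rate]
    lo = np.array([0.0, 0.5, 0.3, 0.0])
    hi = np.array([max(5.0 * ymax, 1e-6), 100.0, 6.0, max(ymax, 1e-6)])

    def resid(p):
        return hyperbolic_ratio(c, *p) - y

    best = None
    for c50_0 in c50_starts:
        for n_0 in n_starts:
            x0 = np.clip(
                np.array([max(rng_y, 1e-3), c50_0, n_0, max(float(np.min(y)), 0.0)]),
                lo, hi,
            )
            try:
                sol = optimize.least_squares(resid, x0, bounds=(lo, hi), method="trf")
            except Exception:  # pragma: no cover - defensive
                continue
            sse = float(sol.fun @ sol.fun)
            if best is None or sse < best[1]:
                best = (sol.x, sse)
    if best is None:
        raise RuntimeError("no CRF fit start converged")
    p, sse = best
    params = CRFParams(r_max=float(p[0]), c50=float(p[1]), n=float(p[2]), m=float(p[3]))
    return params, sse


def fit_crf_grid(contrasts, mean_rates, n_c50=50, n_n=20, n_rmax=50, n_m=20):
    """Brute-force grid search over the CRF parameter box (diagnostic oracle).

    Exhaustive SSE evaluation over a dense (r_max, c50, n, m) grid spanning the
    same bounds as :func:`fit_crf`.  Used as an independent lower-quality
    optimizer to bound the SSE of the nonlinear fit.
    """
    c = np.asarray(contrasts, float)
    y = np.asarray(mean_rates, float)
    ymax = float(np.max(y))
    c50s = np.geomspace(0.5, 100.0, n_c50)
    ns = np.linspace(0.3, 6.0, n_n)
    rmaxs = np.linspace(0.0, 5.0 * max(ymax, 1e-6), n_rmax)
    ms = np.linspace(0.0, max(ymax, 1e-6), n_m)

    # f_k(c) = c^n/(c^n + c50^n), one row per (c50, n) pair
    cc50, nn = np.meshgrid(c50s, ns, indexing="ij")
    pairs = np.stack([cc50.ravel(), nn.ravel()], axis=1)
    f = np.empty((pairs.shape[0], c.size))
    for k, (c50_k, n_k) in enumerate(pairs):
        cn = np.where(c > 0, c**n_k, 0.0)
        f[k] = cn / (cn + c50_k**n_k)

    # SSE(r, m | f) expands into moments of y and f: avoids materializing the
    # full 4-D grid of residual vectors.
    sy = float(np.sum(y))
    syy = float(y @ y)
    sf = f.sum(axis=1)                     # (K,)
    sff = np.einsum("ki,ki->k", f, f)      # (K,)
    syf = f @ y                            # (K,)
    nlev = c.size

    r = rmaxs[None, :, None]
    m = ms[None, None, :]
    sse = (
        syy
        - 2.0 * m * sy
        - 2.0 * r * syf[:, None, None]
        + nlev * m**2
        + 2.0 * m * r * sf[:, None, None]
        + r**2 * sff[:, None, None]
    )
    k, ir, im = np.unravel_index(np.argmin(sse), sse.shape)
    c50_b, n_b = pairs[k]
    best = CRFParams(float(rmaxs[ir]), float(c50_b), float(n_b), float(max(ms[im], 0.0)))
    return best, float(sse[k, ir, im])


# ---------------------------------------------------------------------------
# indices


def ami_of_values(v_in, v_away):
    """(in - away) / (in + away); nan where the denominator vanishes."""
    v_in = np.asarray(v_in, float)
    v_away = np.asarray(v_away, float)
    denom = v_in + v_away
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(denom != 0, (v_in - v_away) / denom, np.nan)
    return out if out.ndim else float(out)


def ami_curve(crf_in: CRFParams, crf_away: CRFParams, contrasts):
    """Per-contrast attentional modulation index of the two fitted CRFs."""
    c = np.asarray(contrasts, float)
    return ami_of_values(crf_in.rate(c), crf_away.rate(c))


def ami_params(crf_in: CRFParams, crf_away: CRFParams) -> dict[str, float]:
    """AMI applied to each fitted parameter pair (r_max, c50, n, m)."""
    a, b = crf_in.as_array(), crf_away.as_array()
    return {name: float(ami_of_values(a[i], b[i])) for i, name in enumerate(PARAM_NAMES)}


def compute_cdi(ami_by_contrast, contrasts, c50_away, eps=1e-3):
    """Contrast dependence index of a single unit.

    CDI = (mean AMI over c <= c50_away  -  mean AMI over c > c50_away)
          / (mean AMI over all contrasts).

    Contrasts equal to the threshold count as low.  Returns ``(cdi, valid)``;
    ``valid`` is False (and cdi is nan) when either side of the split is empty
    or the overall mean AMI is within ``eps`` of zero (unstable denominator).
    """
    ami = np.asarray(ami_by_contrast, float)
    c = np.asarray(contrasts, float)
    low = c <= c50_away
    high = ~low
    if not low.any() or not high.any():
        return float("nan"), False
    overall = float(np.nanmean(ami))
    if abs(overall) < eps:
        return float("nan"), False
    cdi = (float(np.nanmean(ami[low])) - float(np.nanmean(ami[high]))) / overall
    return cdi, True


# ---------------------------------------------------------------------------
# trial-level operations


def _window_rates(trials_ms, window):
    """Per-trial firing rate (spikes/s) within a half-open window in ms."""
    lo, hi = window
    width_s = (hi - lo) / 1000.0
    return np.array(
        [np.count_nonzero((t >= lo) & (t < hi)) / width_s for t in trials_ms], float
    )


def spike_counts_to_rates(trial_set, unit_index, condition):
    """Per-contrast mean rate +/- SEM in the 60-260 ms spike-count window.

    Returns a DataFrame with columns contrast, mean_rate, sem, n_trials.
    """
    spikes = trial_set.spikes[unit_index][condition]
    rows = []
    for ci, contrast in enumerate(trial_set.contrasts):
        trials = spikes[ci]
        if len(trials) == 0:
            raise ValueError(f"no trials at contrast {contrast} for condition {condition}")
        r = _window_rates(trials, COUNT_WINDOW)
        sem = float(r.std(ddof=1) / np.sqrt(r.size)) if r.size > 1 else 0.0
        rows.append((float(contrast), float(r.mean()), sem, r.size))
    return pd.DataFrame(rows, columns=["contrast", "mean_rate", "sem", "n_trials"])


def screen_visual_responsiveness(trial_set, unit_index, alpha=0.05):
    """One-sided rank test: evoked rate at the highest contrast > baseline rate.

    Evoked rates are taken in the 60-260 ms window of highest-contrast trials
    (both attention conditions pooled); baseline rates in the -200-0 ms window
    of the same trials.
    """
    ci = int(np.argmax(trial_set.contrasts))
    evoked, base = [], []
    for condition in trial_set.conditions:
        for t in trial_set.spikes[unit_index][condition][ci]:
            t = np.asarray(t, float)
            evoked.append(np.count_nonzero((t >= COUNT_WINDOW[0]) & (t < COUNT_WINDOW[1]))
                          / ((COUNT_WINDOW[1] - COUNT_WINDOW[0]) / 1000.0))
            base.append(np.count_nonzero((t >= BASELINE_WINDOW[0]) & (t < BASELINE_WINDOW[1]))
                        / ((BASELINE_WINDOW[1] - BASELINE_WINDOW[0]) / 1000.0))
    evoked = np.asarray(evoked)
    base = np.asarray(base)
    if evoked.sum() == 0 and base.sum() == 0:
        return False
    if np.all(evoked == base):
        return False
    p = stats.mannwhitneyu(evoked, base, alternative="greater").pvalue
    return bool(p < alpha)


def analyze_unit(trial_set, unit_index, cdi_eps=0.01):
    """Fit both attention conditions of one unit and derive its AMI profile.

    The CDI is a ratio whose denominator (mean AMI) must reflect real
    attentional modulation to be meaningful.  A unit's CDI is flagged invalid
    unless its overall attend-in vs attend-away rate difference is resolved:
    per-contrast z-scores of the mean-rate difference are combined across
    contrasts (Stouffer) and |Z| must reach 1.96.  This gate is dominated by
    the high-rate (high-contrast) comparisons and is therefore nearly
    independent of the CDI numerator (the low-minus-high AMI contrast), so it
    does not select on the quantity being estimated.
    """
    fits, tbls = {}, {}
    for condition in ("attend_in", "attend_away"):
        tbl = spike_counts_to_rates(trial_set, unit_index, condition)
        fits[condition], _ = fit_crf(tbl["contrast"].values, tbl["mean_rate"].values)
        tbls[condition] = tbl
    crf_in, crf_away = fits["attend_in"], fits["attend_away"]
    # blank (0%) trials participate in the fit, anchoring the baseline; the
    # attention indices are evaluated at the stimulus contrasts only
    stim = np.asarray(trial_set.contrasts, float) > 0
    contrasts = np.asarray(trial_set.contrasts, float)[stim]
    for condition in tbls:
        tbls[condition] = tbls[condition][stim].reset_index(drop=True)
    ami = ami_curve(crf_in, crf_away, contrasts)
    # Stouffer-combined z of the per-contrast rate differences
    diff = tbls["attend_in"]["mean_rate"].values - tbls["attend_away"]["mean_rate"].values
    se = np.sqrt(tbls["attend_in"]["sem"].values**2
                 + tbls["attend_away"]["sem"].values**2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, diff / se, 0.0)
    z_comb = float(np.sum(z) / np.sqrt(contrasts.size))
    cdi, valid = compute_cdi(ami, contrasts, crf_away.c50, eps=cdi_eps)
    if abs(z_comb) < 1.96:
        cdi, valid = float("nan"), False
    return AMIProfile(
        contrasts=contrasts,
        ami_by_contrast=ami,
        ami_params=ami_params(crf_in, crf_away),
        mean_ami=float(np.nanmean(ami)),
        cdi=cdi,
        cdi_valid=valid,
        crf_in=crf_in,
        crf_away=crf_away,
    )


def aggregate_by_group(profiles, groups, n_boot=10_000, seed=0, cdi_abs_max=10.0):
    """Group-level AMI/CDI summaries with bootstrap CIs.

    Parameters
    ----------
    profiles : sequence of AMIProfile
    groups : sequence of hashable group keys, one per profile (e.g. (cls, layer))
    cdi_abs_max : units with |CDI| above this (or invalid CDI) are excluded
        from the CDI summary as outliers.

    Returns a dict mapping group key -> summary dict with keys
    ``n_units, mean_ami_curve, sem_ami_curve, contrasts, mean_cdi, cdi_ci,
    n_cdi_units``.
    """
    from .bootstats import boot_mean

    groups = list(groups)
    if len(groups) != len(profiles):
        raise ValueError("one group key per profile required")
    out = {}
    for g in sorted(set(groups), key=str):
        idx = [i for i, gg in enumerate(groups) if gg == g]
        if len(idx) < 3:
            warnings.warn(f"group {g!r} has <3 units; omitted")
            continue
        profs = [profiles[i] for i in idx]
        curves = np.vstack([p.ami_by_contrast for p in profs])
        mean_curve = np.nanmean(curves, axis=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sem_curve = np.nanstd(curves, axis=0, ddof=1) / np.sqrt(curves.shape[0])
        cdis = np.array([p.cdi for p in profs if p.cdi_valid and abs(p.cdi) <= cdi_abs_max])
        summary = {
            "n_units": len(profs),
            "contrasts": profs[0].contrasts.copy(),
            "mean_ami_curve": mean_curve,
            "sem_ami_curve": sem_curve,
            "mean_ami": float(np.nanmean(curves)),
            "n_cdi_units": int(cdis.size),
            "mean_cdi": float(np.mean(cdis)) if cdis.size else float("nan"),
            "cdi_ci": (float("nan"), float("nan")),
        }
        if cdis.size >= 3:
            br = boot_mean(cdis, n_boot=n_boot, seed=seed)
            summary["cdi_ci"] = (br.ci_low, br.ci_high)
        out[g] = summary
    return out
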