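"""End-to-end study replica: simulate -> classify -> fit -> CDI -> latency ->
mechanistic models, from a single seeded configuration.

The report asserts qualitative claims only (cluster count, sign/CI-exclusion
of group CDIs, latency ordering, model monotonicity); no empirical numbers
are hard-coded.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import crf, latency, synth, waveforms
from .bootstats import boot_mean
from .einet import NetConfig, ei_correlation_vs_sigma
from .normmodel import NMConfig, sweep_fields

__all__ = ["RunConfig", "run_all"]


@dataclass
class RunConfig:
    seed: int = 7
    preset: str = "laminar_gain"          # or "null"
    n_units: int = 240
    n_trials: int = 60
    n_boot: int = 5000
    waveform_noise_sd: float = 0.02
    waveform_fs: float = 30_000.0
    n_restarts: int = 200               # meta-k-means restarts
    run_norm_model: bool = True
    run_ei_network: bool = True
    ei_n_seeds: int = 2
    ei_sigma_values: tuple = (1.0, 2.0, 4.0)
    nm_stimfield_sizes: tuple = (0.5, 1.0, 2.0)
    nm_suppfield_sizes: tuple = (1.5, 3.0, 6.0)
    out_dir: str | None = None
    population: synth.PopulationConfig = field(default=None)
    trials: synth.TrialConfig = field(default=None)

    def __post_init__(self):
        if self.preset not in ("laminar_gain", "null"):
            raise ValueError(f"unknown preset {self.preset!r}")
        scenario = (synth.laminar_gain_scenario() if self.preset == "laminar_gain"
                    else synth.null_scenario())
        if self.population is None:
            self.population = synth.PopulationConfig(n_units=self.n_units,
                                                     scenario=scenario)
        if self.trials is None:
            self.trials = synth.TrialConfig(
                n_trials_per_contrast_per_condition=self.n_trials)


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return [_jsonable(v) for v in x]
    if isinstance(x, dict):
        return {str(k): _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    if isinstance(x, float) and not np.isfinite(x):
        return None
    return x


def run_all(config: RunConfig):
    """Run every stage; returns the report dict (and writes CSV/JSON outputs
    when ``config.out_dir`` is set)."""
    report = {"seed": config.seed, "preset": config.preset}
    rng_seed = int(config.seed)

    # --- stage 1: synthesize ------------------------------------------------
    units = synth.make_population(config.population, seed=rng_seed)
    trial_set = synth.simulate_trials(units, config.trials, seed=rng_seed + 1)

    # --- stage 2: waveform classification ----------------------------------
    wf = np.vstack([
        synth.make_waveform(u.ptd_true, fs=config.waveform_fs,
                            noise_sd=config.waveform_noise_sd,
                            seed=rng_seed * 100_003 + u.unit_id)[1]
        for u in units])
    cls_res = waveforms.classify_units(wf, fs=config.waveform_fs,
                                       n_restarts=config.n_restarts,
                                       seed=rng_seed + 2)
    true_cls = np.array([synth.CLASSES.index(u.cls) for u in units])
    agreement = None
    if cls_res["k"] == len(synth.CLASSES):
        agreement = waveforms.match_labels(true_cls, cls_res["labels"])
    report["classification"] = {
        "k_aic": cls_res["k_aic"], "k_bic": cls_res["k_bic"], "k": cls_res["k"],
        "dip": cls_res["dip"], "dip_p": cls_res["dip_p"],
        "agreement_with_ground_truth": agreement,
    }
    class_names = (cls_res["class_names"] if cls_res["k"] == 3
                   else [u.cls for u in units])

    # --- stage 3: CRF fits, AMI, CDI ----------------------------------------
    profiles, keep = [], []
    for i in range(len(units)):
        if not crf.screen_visual_responsiveness(trial_set, i):
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            profiles.append(crf.analyze_unit(trial_set, i))
        keep.append(i)
    report["n_responsive"] = len(keep)
    groups = [(class_names[i], units[i].layer) for i in keep]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        group_summary = crf.aggregate_by_group(
            profiles, groups, n_boot=config.n_boot, seed=rng_seed + 3)
    cdi_table = {}
    for (cls_name, layer), summ in group_summary.items():
        lo, hi = summ["cdi_ci"]
        cdi_table[f"{cls_name}|{layer}"] = {
            "n_units": summ["n_units"], "n_cdi_units": summ["n_cdi_units"],
            "mean_cdi": summ["mean_cdi"], "ci_low": lo, "ci_high": hi,
            "ci_excludes_zero_above": bool(np.isfinite(lo) and lo > 0),
            "ci_spans_zero": bool(np.isfinite(lo) and lo <= 0 <= hi),
            "mean_ami": summ["mean_ami"],
        }
    report["cdi_by_class_layer"] = cdi_table

    unit_rows = []
    for i, prof in zip(keep, profiles):
        row = {"unit_id": i, "class": class_names[i], "layer": units[i].layer,
               "mean_ami": prof.mean_ami, "cdi": prof.cdi,
               "cdi_valid": prof.cdi_valid}
        for cond, fit in (("in", prof.crf_in), ("away", prof.crf_away)):
            for name, v in zip(crf.PARAM_NAMES, fit.as_array()):
                row[f"{name}_{cond}"] = v
        for name, v in prof.ami_params.items():
            row[f"ami_{name}"] = v
        unit_rows.append(row)
    unit_df = pd.DataFrame(unit_rows)

    # --- stage 4: response latency ------------------------------------------
    top = np.argsort(trial_set.contrasts)[-3:]
    rts = []
    for i in keep:
        trials = []
        for cond in trial_set.conditions:
            for ci in top:
                trials.extend(trial_set.spikes[i][cond][ci])
        grid = np.arange(trial_set.trial_span[0], trial_set.trial_span[1] + 1.0)
        est = latency.adaptive_rate(trials, time_grid=grid)
        rts.append(latency.response_time(trials, est, seed=rng_seed + 5 + i))
    lat_summary, lat_tests = latency.class_latency_summary(
        rts, [class_names[i] for i in keep], n_boot=config.n_boot,
        seed=rng_seed + 4)
    report["latency"] = {
        "class_means": {k: {"mean": v.point, "ci": [v.ci_low, v.ci_high]}
                        for k, v in lat_summary.items()},
        "tests": {f"{a}|{b}": t for (a, b), t in lat_tests.items()},
    }
    unit_df["response_time_ms"] = [rts[keep.index(i)] if i in keep else None
                                   for i in unit_df["unit_id"]]

    # --- stage 5: normalization model ---------------------------------------
    nm_df = None
    if config.run_norm_model:
        cdi = sweep_fields(NMConfig(), config.nm_stimfield_sizes,
                           config.nm_suppfield_sizes)
        nm_df = pd.DataFrame(cdi, index=list(config.nm_stimfield_sizes),
                             columns=list(config.nm_suppfield_sizes))
        report["norm_model"] = {
            "cdi_matrix": cdi.tolist(),
            "nonincreasing_in_suppfield": bool(np.all(np.diff(cdi, axis=1) <= 1e-6)),
            "nonincreasing_in_stimfield": bool(np.all(np.diff(cdi, axis=0) <= 1e-6)),
        }

    # --- stage 6: E-I network -----------------------------------------------
    ei_df = None
    if config.run_ei_network:
        rows = ei_correlation_vs_sigma(NetConfig(), config.ei_sigma_values,
                                       param="sigma_i",
                                       n_seeds=config.ei_n_seeds,
                                       seed0=rng_seed + 6)
        ei_df = pd.DataFrame(rows)
        means = ei_df.groupby("sigma")["win_mean"].mean()
        report["ei_network"] = {
            "sigma_i": list(means.index),
            "mean_window_ccg": list(means.values),
            "decreasing_in_sigma_i": bool(np.all(np.diff(means.values) < 0)),
        }

    # --- outputs -------------------------------------------------------------
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame({
            "unit_id": range(len(units)),
            "ptd_ms": cls_res["ptd_ms"],
            "class": class_names,
            "layer": [u.layer for u in units],
            "true_class": [u.cls for u in units],
        }).to_csv(out / "units.csv", index=False)
        unit_df.to_csv(out / "crf.csv", index=False)
        if nm_df is not None:
            nm_df.to_csv(out / "nm_cdi.csv")
        if ei_df is not None:
            ei_df.to_csv(out / "ccg_sigma.csv", index=False)
        with open(out / "report.json", "w") as fh:
            json.dump(_jsonable(report), fh, indent=2, sort_keys=True)
    return report
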