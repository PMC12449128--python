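"""End-to-end synthetic study pipeline.

Simulates a group of observer agents performing the marble task, generates
their belief-coupled BOLD runs, runs the LS-S / SD_BOLD analysis, and
performs the group-level inference: task PLS on the SD_BOLD maps with
polynomial trend tests, behavioral PLS of SD_BOLD change against median
estimation error, and rank-based regressions of the latent SD_BOLD change
on the fitted observer parameters. All randomness derives from one master
seed via named substreams, so a rerun with the same config and seed
reproduces the report byte for byte.
"""

from __future__ import annotations

import copy
import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior, fitting, pls, task
from .bold_sim import NoiseSpec, generate_subject_bold, make_layout
from .glm import SAMPLE_CONDITIONS, BoldVariabilityModel, parametric_uncertainty_glm
from .observer import ObserverSpec, trial_trajectory

__all__ = ["DEFAULT_CONFIG", "validate_config", "run_full_pipeline", "draw_population"]

DEFAULT_CONFIG = {
    "seed": 0,
    "task": {
        "n_jars": 18,
        "p_range": [0.1, 0.91],
        "n_blocks": 3,
        "sizes": [1, 5, 9],
    },
    "agents": {
        "n_subjects": 30,
        "family": "bayes_rho_sigma",
        "missing_rate": 0.0,
        # population follows the fitted group values: rho median 2.45 with a
        # heavy right tail (group SD ~4.2), sigma median 0.10
        "rho_median": 2.45,
        "rho_log_sd": 1.1,
        "sigma_median": 0.10,
        "sigma_log_sd": 0.2,
        "sigma_range": [0.03, 0.3],
    },
    "neuro": {
        "tr": 0.645,
        "gain": 1.0,
        "base": 0.05,
        "null_sd": 0.2,
        "white_sd": 0.2,
        "grid": [12, 12, 12],
        "mask_size": [6, 6, 6],
        "effect_size": [6, 3, 6],
    },
    "analysis": {
        "fit_families": ["bayes_rho_sigma"],
        "n_starts": 10,
        "n_perm": 500,
        "n_boot": 500,
        "bsr_threshold": 3.0,
        "cluster_min": 25,
        "rank": True,
        "cooks_screen": True,
        # parametric posterior-variance GLM + spatially matched latent
        # control analysis; off by default (the core study path does not
        # need it and it doubles the per-subject GLM work)
        "parametric_glm": False,
    },
}

_STREAMS = ("task", "agents", "bold", "fit", "perm", "boot")


def _substreams(seed: int) -> dict:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(ss) for name, ss in zip(_STREAMS, children)}


def validate_config(config) -> dict:
    """Normalize a config mapping or YAML path against the default schema.

    Unknown keys and bound violations raise; missing keys are filled with
    defaults. Idempotent.
    """
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh) or {}
    if not isinstance(config, dict):
        raise TypeError("config must be a mapping or a YAML path")
    out = copy.deepcopy(DEFAULT_CONFIG)
    unknown = set(config) - set(out)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key, val in config.items():
        if isinstance(out[key], dict):
            bad = set(val) - set(out[key])
            if bad:
                raise ValueError(f"unknown keys in {key!r} block: {sorted(bad)}")
            out[key].update(val)
        else:
            out[key] = val
    if out["agents"]["rho_median"] < 1:
        raise ValueError("rho_median must be >= 1 (prior width bound)")
    if out["agents"]["sigma_median"] <= 0:
        raise ValueError("sigma_median must be positive")
    lo, hi = out["task"]["p_range"]
    if not (0 < lo < hi < 1):
        raise ValueError("p_range must satisfy 0 < low < high < 1")
    out["seed"] = int(out["seed"])
    return out


def _stratified_normal(n: int, rng: np.random.Generator) -> np.ndarray:
    """Stratified standard-normal draws (one per probability stratum).

    Latin-hypercube-style sampling keeps small simulated groups
    representative of the population (tails included) without removing
    randomness; the strata are randomly permuted across subjects.
    """
    u = (np.arange(n) + rng.uniform(size=n)) / n
    from scipy.stats import norm

    return rng.permutation(norm.ppf(u))


def draw_population(agents_cfg: dict, rng: np.random.Generator) -> pd.DataFrame:
    """Draw observer parameters for a simulated group.

    rho is 1 plus a lognormal (median rho_median - 1), keeping the support
    on [1, inf) with a heavy right tail as seen in fitted groups; sigma is
    lognormal around sigma_median, clipped to sigma_range. Both draws are
    stratified over quantiles so every simulated group spans the
    population range.
    """
    n = agents_cfg["n_subjects"]
    rho = 1.0 + np.exp(
        np.log(max(agents_cfg["rho_median"] - 1.0, 1e-6))
        + agents_cfg["rho_log_sd"] * _stratified_normal(n, rng)
    )
    sigma = np.clip(
        np.exp(
            np.log(agents_cfg["sigma_median"])
            + agents_cfg["sigma_log_sd"] * _stratified_normal(n, rng)
        ),
        *agents_cfg["sigma_range"],
    )
    return pd.DataFrame({"rho": rho, "sigma": sigma})


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]


def run_full_pipeline(config=None, out_dir=None) -> dict:
    """Execute the full synthetic study; returns the machine-readable report.

    Stages: task design -> agent simulation -> observer-model fitting ->
    behavior metrics -> BOLD synthesis -> LS-S / SD_BOLD -> task and
    behavioral PLS -> latent regressions. Writes ``report.json`` (and the
    per-subject tables) into ``out_dir`` when given.
    """
    cfg = validate_config(config or {})
    rngs = _substreams(cfg["seed"])
    report = {"config_hash": _config_hash(cfg), "seed": cfg["seed"], "stages": {}}
    timings = {}

    def _stage(name):
        timings[name] = time.perf_counter()

    def _done(name):
        timings[name] = round(time.perf_counter() - timings[name], 3)

    # --- task design -------------------------------------------------
    _stage("task")
    tcfg = cfg["task"]
    jars = task.make_jars(tcfg["n_jars"], *tcfg["p_range"])
    n_sub = cfg["agents"]["n_subjects"]
    sessions = [
        task.build_session(
            jars, n_blocks=tcfg["n_blocks"], rng=rngs["task"], sizes=tcfg["sizes"]
        )
        for _ in range(n_sub)
    ]
    _done("task")
    report["stages"]["task"] = {
        "n_jars": len(jars),
        "n_trials_per_subject": sessions[0].n_trials,
        "n_subjects": n_sub,
    }

    # --- agents ------------------------------------------------------
    _stage("agents")
    family = cfg["agents"]["family"]
    params = draw_population(cfg["agents"], rngs["agents"])
    specs = [
        ObserverSpec(family, {k: float(v) for k, v in row.items()})
        for _, row in params.iterrows()
    ]
    datasets = fitting.simulate_agents(
        specs, sessions, rngs["agents"], missing_rate=cfg["agents"]["missing_rate"]
    )
    _done("agents")

    # --- model fitting ----------------------------------------------
    _stage("fit")
    acfg = cfg["analysis"]
    fits_by_family = {
        fam: [
            fitting.fit_subject(fam, trials, n_starts=acfg["n_starts"], rng=rngs["fit"])
            for trials in datasets
        ]
        for fam in acfg["fit_families"]
    }
    fitted = fits_by_family[family] if family in fits_by_family else fits_by_family[
        next(iter(fits_by_family))
    ]
    fit_params = pd.DataFrame([f.params for f in fitted])
    report["stages"]["fit"] = {
        fam: {"summed_bic": float(sum(f.bic for f in fits))}
        for fam, fits in fits_by_family.items()
    }
    if len(fits_by_family) > 1:
        comparison = fitting.compare_models(fits_by_family)
        report["stages"]["fit"]["winner"] = comparison.attrs["winner"]
    _done("fit")

    # --- behavior metrics -------------------------------------------
    _stage("behavior")
    summary = behavior.subject_summary(datasets)
    rows = []
    for i, trials in enumerate(datasets):
        for t in trials:
            if t.valid:
                rows.append(
                    {
                        "subject": i,
                        "error": behavior.estimation_error(t),
                        "distance": abs(t.jar_p_blue - 0.5),
                    }
                )
    long = pd.DataFrame(rows)
    bias = behavior.trialwise_bias_test(long)
    report["stages"]["behavior"] = {
        "median_error_range": [
            float(summary["median_error"].min()),
            float(summary["median_error"].max()),
        ],
        "extreme_jar_bias_mean": float(summary["extreme_jar_bias"].mean()),
        "trialwise_bias_F": bias["F"],
        "trialwise_bias_p": bias["p"],
    }
    _done("behavior")

    # --- BOLD synthesis + SD_BOLD -----------------------------------
    _stage("bold")
    ncfg = cfg["neuro"]
    layout = make_layout(
        shape=tuple(ncfg["grid"]),
        mask_size=tuple(ncfg["mask_size"]),
        effect_size=tuple(ncfg["effect_size"]),
        gain=ncfg["gain"],
        base=ncfg["base"],
        null_sd=ncfg["null_sd"],
    )
    noise = NoiseSpec(white_sd=ncfg["white_sd"])
    sd_stack, slope_stack, uncertainty_betas = [], [], []
    unbiased = ObserverSpec("bayes_rho_sigma", {"rho": 1.0, "sigma": 0.1})
    for spec, session in zip(specs, sessions):
        trajectories = [trial_trajectory(spec, t.samples) for t in session.trials]
        runs = generate_subject_bold(
            session, trajectories, layout, noise=noise, rng=rngs["bold"], tr=ncfg["tr"]
        )
        res = BoldVariabilityModel(runs).fit()
        order = [res.sd_map.conditions.index(c) for c in SAMPLE_CONDITIONS]
        sd_stack.append(res.sd_map.sd[order])
        slope_stack.append(res.slopes)
        if acfg["parametric_glm"]:
            # modulators: posterior variance of the unbiased observer after
            # each presented sample, in run event order
            modulators = []
            for run in runs:
                samples = run.events[
                    run.events["trial_type"].isin(SAMPLE_CONDITIONS)
                ]
                traj_by_id = {
                    t.trial_id: trial_trajectory(unbiased, t.samples)
                    for t in session.block(run.run_id)
                }
                modulators.append(
                    [
                        traj_by_id[int(ev["trial_id"])][
                            int(ev["trial_type"].split("_")[1])
                        ].variance
                        for _, ev in samples.iterrows()
                    ]
                )
            uncertainty_betas.append(parametric_uncertainty_glm(runs, modulators))
    sd_stack = np.array(sd_stack)  # subject x condition x voxel
    slope_stack = np.array(slope_stack)  # subject x voxel
    report["stages"]["bold"] = {
        "n_voxels": layout.n_voxels,
        "n_effect_voxels": int(layout.effect_index.size),
        "median_sd_by_period": [
            float(np.median(sd_stack[:, k, layout.effect_index])) for k in range(5)
        ],
    }
    _done("bold")

    # --- group inference ---------------------------------------------
    _stage("inference")
    perm_seed = int(rngs["perm"].integers(2**31))
    boot_seed = int(rngs["boot"].integers(2**31))
    task_res = pls.task_pls(sd_stack, n_perm=acfg["n_perm"], seed=perm_seed)
    trend = pls.polynomial_contrasts(task_res.brain_scores[:, :, 0])
    errors = summary[
        "median_error_winsorized"
        if "median_error_winsorized" in summary
        else "median_error"
    ].to_numpy()
    model = pls.BehavioralPLS(slope_stack, errors, rank=acfg["rank"])
    beh_res = model.fit(n_perm=acfg["n_perm"], n_boot=acfg["n_boot"], seed=boot_seed)
    kept = np.arange(n_sub)
    if acfg["cooks_screen"]:
        flagged = pls.cooks_screen(beh_res.brain_scores[:, 0], errors)
        if flagged.size:
            kept = np.setdiff1d(kept, flagged)
            model = pls.BehavioralPLS(
                slope_stack[kept], errors[kept], rank=acfg["rank"]
            )
            beh_res = model.fit(
                n_perm=acfg["n_perm"], n_boot=acfg["n_boot"], seed=boot_seed
            )
    bsr_vol = layout.unmask(np.abs(beh_res.bsr[:, 0]) > acfg["bsr_threshold"])
    pruned, clusters = pls.cluster_threshold(
        bsr_vol, min_size=acfg["cluster_min"], bsr_volume=layout.unmask(beh_res.bsr[:, 0])
    )
    latent_slope = beh_res.brain_scores[:, 0]
    reg = pls.latent_regression(
        latent_slope,
        fit_params.iloc[kept][["rho", "sigma"]]
        if {"rho", "sigma"} <= set(fit_params)
        else fit_params.iloc[kept],
        rank=acfg["rank"],
    )
    uncertainty_report = None
    if acfg["parametric_glm"]:
        # latent uncertainty-beta analysis plus the spatially matched
        # control: does SD_BOLD change predict error beyond the parametric
        # uncertainty modulation expressed in the same spatial pattern?
        unc = np.array(uncertainty_betas)[kept]
        unc_res = pls.BehavioralPLS(unc, errors[kept], rank=acfg["rank"]).fit(
            n_perm=acfg["n_perm"], seed=boot_seed
        )
        matched = pls.spatially_matched_latent(beh_res.saliences[:, 0], unc)
        joint = pls.latent_regression(
            errors[kept],
            pd.DataFrame(
                {"latent_sdbold_change": latent_slope, "matched_uncertainty": matched}
            ),
            rank=acfg["rank"],
        )
        uncertainty_report = {
            "uncertainty_pls_p": float(unc_res.perm_p[0]),
            "uncertainty_latent_correlation": float(unc_res.latent_correlation),
            "joint_regression": {
                row["predictor"]: {
                    "t": float(row["t"]),
                    "p": float(row["p"]),
                    "semi_partial_eta2": float(row["semi_partial_eta2"]),
                }
                for _, row in joint["predictors"].iterrows()
            },
        }

    report["stages"]["inference"] = {
        "task_pls_p": float(task_res.perm_p[0]),
        "trend": {
            row["order"]: {"F": float(row["F"]), "p": float(row["p"])}
            for _, row in trend.iterrows()
        },
        "behavioral_pls_p": float(beh_res.perm_p[0]),
        "latent_correlation": float(beh_res.latent_correlation),
        "n_subjects_after_screen": int(kept.size),
        "n_robust_clusters": int(len(clusters)),
        "latent_regression": {
            row["predictor"]: {
                "t": float(row["t"]),
                "p": float(row["p"]),
                "semi_partial_eta2": float(row["semi_partial_eta2"]),
            }
            for _, row in reg["predictors"].iterrows()
        },
    }
    if uncertainty_report is not None:
        report["stages"]["inference"]["uncertainty_glm"] = uncertainty_report
    _done("inference")

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        # timings go to a side log so report.json is reproducible bit for bit
        (out / "timings.json").write_text(json.dumps(timings, indent=2, sort_keys=True))
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        summary.to_csv(out / "behavior_summary.tsv", sep="\t", index=False)
        fit_params.to_csv(out / "fitted_parameters.tsv", sep="\t", index=False)
        clusters.to_csv(out / "clusters.tsv", sep="\t", index=False)
    return report
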