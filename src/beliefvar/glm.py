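"""Event-related GLM machinery and across-trial BOLD variability (SD_BOLD).

Single-trial response amplitudes are estimated with the least-squares-single
(LS-S) scheme: for every event, one GLM is fitted containing a regressor for
that event alone and a second regressor pooling all other events (of every
condition), each convolved with the canonical HRF and its temporal and
dispersion derivatives. SD_BOLD for a sample period is the across-trial
standard deviation of the canonical single-trial betas; its linear slope
over the five sample periods is the per-voxel SD_BOLD change.

The canonical double-gamma HRF (peak ~6 s, undershoot ~16 s, ratio 1/6) and
its derivatives come from nilearn.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal
from nilearn.glm.first_level.hemodynamic_models import (
    spm_dispersion_derivative,
    spm_hrf,
    spm_time_derivative,
)

__all__ = [
    "hrf_basis",
    "build_design",
    "DesignMatrix",
    "TrialBetaMatrix",
    "SDBoldMap",
    "lss_betas",
    "sd_bold",
    "sdbold_change",
    "condition_mean_glm",
    "condition_change",
    "parametric_uncertainty_glm",
    "split_half_reliability",
    "BoldVariabilityModel",
    "VariabilityResults",
    "SAMPLE_CONDITIONS",
]

SAMPLE_CONDITIONS = tuple(f"sample_{i}" for i in range(1, 6))
BASIS_TAGS = ("canonical", "derivative", "dispersion")
#: events whose HRF response would be truncated by the run end are dropped
FINAL_WINDOW_S = 20.0
_OVERSAMPLING = 10
_HRF_LENGTH_S = 32.0


def hrf_basis(tr: float, length: float = _HRF_LENGTH_S) -> np.ndarray:
    """Canonical HRF plus temporal and dispersion derivatives, sampled at tr.

    Returns an array of shape (3, n_samples); the canonical function is
    normalized to unit peak, the derivatives to unit maximum magnitude.
    """
    if tr <= 0:
        raise ValueError("tr must be positive")
    kwargs = dict(oversampling=1, time_length=length)
    rows = [
        spm_hrf(tr, **kwargs),
        spm_time_derivative(tr, **kwargs),
        spm_dispersion_derivative(tr, **kwargs),
    ]
    basis = np.vstack([r / np.max(np.abs(r)) for r in rows])
    return basis


def _event_regressors(onsets, durations, amplitudes, tr, n_scans) -> np.ndarray:
    """Convolve a set of events with the 3-function basis.

    Events are unit-height boxcars over [onset, onset + duration) on a
    fine grid (tr / 10), convolved and then sampled at scan times.
    Returns (n_scans, n_events, 3).
    """
    onsets = np.atleast_1d(np.asarray(onsets, float))
    durations = np.atleast_1d(np.asarray(durations, float))
    amplitudes = np.atleast_1d(np.asarray(amplitudes, float))
    dt = tr / _OVERSAMPLING
    n_hi = n_scans * _OVERSAMPLING
    sticks = np.zeros((n_hi, onsets.size))
    for j, (on, dur, amp) in enumerate(zip(onsets, durations, amplitudes)):
        i0 = int(np.round(on / dt))
        i1 = max(i0 + 1, int(np.round((on + dur) / dt)))
        sticks[i0 : min(i1, n_hi), j] = amp
    basis = hrf_basis(dt)
    out = np.empty((n_scans, onsets.size, 3))
    for k in range(3):
        conv = signal.fftconvolve(sticks, basis[k][:, None], axes=0)[:n_hi]
        out[:, :, k] = conv[:: _OVERSAMPLING]
    return out


@dataclass
class DesignMatrix:
    """Time x regressor design with named columns and basis tags."""

    frame: pd.DataFrame
    conditions: list
    basis_tags: dict = field(default_factory=dict)

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy()

    @property
    def names(self) -> list:
        return list(self.frame.columns)


def build_design(events: pd.DataFrame, tr: float, n_scans: int) -> DesignMatrix:
    """Full-run design: per-condition boxcars x 3 basis functions + constant."""
    run_end = n_scans * tr
    if (events["onset"] >= run_end).any():
        raise ValueError("events past run end")
    cols, names, tags = [], [], {}
    sample_conds = [c for c in SAMPLE_CONDITIONS if c in set(events["trial_type"])]
    other_conds = sorted(set(events["trial_type"]) - set(SAMPLE_CONDITIONS))
    for cond in sample_conds + other_conds:
        sel = events[events["trial_type"] == cond]
        if sel.empty:
            warnings.warn(f"no events for condition {cond!r}; omitted")
            continue
        reg = _event_regressors(
            sel["onset"], sel["duration"], np.ones(len(sel)), tr, n_scans
        ).sum(axis=1)
        for k, tag in enumerate(BASIS_TAGS):
            name = cond if tag == "canonical" else f"{cond}_{tag}"
            cols.append(reg[:, k])
            names.append(name)
            tags[name] = tag
    cols.append(np.ones(n_scans))
    names.append("constant")
    tags["constant"] = "constant"
    frame = pd.DataFrame(np.column_stack(cols), columns=names)
    return DesignMatrix(frame=frame, conditions=sample_conds + other_conds, basis_tags=tags)


@dataclass
class TrialBetaMatrix:
    """Single-trial canonical betas for one condition: trials x voxels."""

    condition: str
    betas: np.ndarray
    trial_ids: list

    @property
    def n_trials(self) -> int:
        return self.betas.shape[0]


@dataclass
class SDBoldMap:
    """Across-trial SD of single-trial betas per sample condition and voxel."""

    conditions: list
    sd: np.ndarray  # (n_conditions, n_voxels)
    n_trials: dict


def _run_lss(run, conditions, prune_final_s: float = FINAL_WINDOW_S) -> dict:
    """LS-S betas for every requested condition of one run.

    The per-event normal equations are assembled from precomputed Gram
    blocks (single-event vs pooled-other regressors share all their cross
    products with the full event set), so each event costs only a 7x7
    solve regardless of run length.
    """
    events = run.events.reset_index(drop=True)
    n_scans, tr = run.n_scans, run.tr
    run_end = n_scans * tr
    n_events = len(events)
    R3 = _event_regressors(
        events["onset"], events["duration"], np.ones(n_events), tr, n_scans
    )
    Rf = R3.reshape(n_scans, n_events * 3)
    total = R3.sum(axis=1)  # pooled regressor over every event
    Y = run.data
    gram = (Rf.T @ Rf).reshape(n_events, 3, n_events, 3)
    ST = gram.sum(axis=2)  # single^T total, (n_events, 3, 3)
    SS = gram[np.arange(n_events), :, np.arange(n_events), :]
    TT = total.T @ total
    s_const = R3.sum(axis=0)  # (n_events, 3)
    t_const = total.sum(axis=0)
    A = (Rf.T @ Y).reshape(n_events, 3, -1)  # single^T Y
    TY = total.T @ Y
    cY = Y.sum(axis=0)
    out = {}
    for condition in conditions:
        is_cond = (events["trial_type"] == condition).to_numpy()
        keep = is_cond & (events["onset"].to_numpy() < run_end - prune_final_s)
        idx = np.flatnonzero(keep)
        if idx.size < 2:
            raise ValueError(f"fewer than 2 usable events for condition {condition!r}")
        betas, trial_ids = [], []
        for i in idx:
            ss, st, sc = SS[i], ST[i], s_const[i]
            so = st - ss
            oo = TT - st - st.T + ss
            oc = t_const - sc
            xtx = np.empty((7, 7))
            xtx[:3, :3] = ss
            xtx[:3, 3:6] = so
            xtx[3:6, :3] = so.T
            xtx[3:6, 3:6] = oo
            xtx[:6, 6] = np.concatenate([sc, oc])
            xtx[6, :6] = xtx[:6, 6]
            xtx[6, 6] = n_scans
            xty = np.vstack([A[i], TY - A[i], cY[None, :]])
            try:
                coef = np.linalg.solve(xtx, xty)
            except np.linalg.LinAlgError as err:
                raise np.linalg.LinAlgError(
                    f"singular LS-S design at trial {events.loc[i, 'trial_id']}"
                    f" (onset {events.loc[i, 'onset']:.2f}s)"
                ) from err
            betas.append(coef[0])  # canonical beta of the single event
            trial_ids.append(int(events.loc[i, "trial_id"]))
        out[condition] = TrialBetaMatrix(
            condition=condition, betas=np.array(betas), trial_ids=trial_ids
        )
    return out


def lss_betas(run, condition: str, prune_final_s: float = FINAL_WINDOW_S) -> TrialBetaMatrix:
    """LS-S single-trial canonical betas for one condition of one run.

    For each event of ``condition``: OLS of the run data on [single event
    x 3 basis, all other events pooled x 3 basis, constant]; the single
    event's canonical beta is retained. Events with onsets in the final
    ``prune_final_s`` seconds of the run are discarded.
    """
    return _run_lss(run, [condition], prune_final_s)[condition]


def _concat_condition(beta_matrices) -> dict:
    """Pool TrialBetaMatrix objects across runs, keyed by condition."""
    pooled = {}
    for bm in beta_matrices:
        pooled.setdefault(bm.condition, []).append(bm)
    return {
        cond: TrialBetaMatrix(
            condition=cond,
            betas=np.vstack([b.betas for b in mats]),
            trial_ids=sum((b.trial_ids for b in mats), []),
        )
        for cond, mats in pooled.items()
    }


def sd_bold(beta_matrices) -> SDBoldMap:
    """Across-trial SD (ddof=1) of canonical betas, pooled across runs."""
    pooled = _concat_condition(beta_matrices)
    conds = [c for c in SAMPLE_CONDITIONS if c in pooled] + sorted(
        set(pooled) - set(SAMPLE_CONDITIONS)
    )
    for cond in conds:
        if pooled[cond].n_trials < 2:
            raise ValueError(f"need >= 2 trials for condition {cond!r}")
    sd = np.vstack([pooled[c].betas.std(axis=0, ddof=1) for c in conds])
    return SDBoldMap(
        conditions=conds, sd=sd, n_trials={c: pooled[c].n_trials for c in conds}
    )


def sdbold_change(sd_map: SDBoldMap, conditions=SAMPLE_CONDITIONS) -> np.ndarray:
    """Per-voxel least-squares slope of SD_BOLD over the sample periods."""
    rows = [sd_map.conditions.index(c) for c in conditions if c in sd_map.conditions]
    if len(rows) < 2:
        raise ValueError("need at least two sample conditions")
    y = sd_map.sd[rows]
    x = np.arange(1, len(rows) + 1, dtype=float)
    xc = x - x.mean()
    return (xc @ (y - y.mean(axis=0))) / (xc @ xc)


def condition_mean_glm(runs) -> pd.DataFrame:
    """Whole-run multi-condition GLM; canonical betas averaged across runs.

    Returns a condition x voxel DataFrame (one row per condition present in
    every run), estimated by OLS per run and combined with an equal-weight
    across-run contrast.
    """
    per_run = []
    for run in runs:
        design = build_design(run.events, run.tr, run.n_scans)
        X = design.values
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise np.linalg.LinAlgError("rank-deficient design")
        coef, *_ = np.linalg.lstsq(X, run.data, rcond=None)
        frame = pd.DataFrame(coef, index=design.names)
        per_run.append(frame.loc[design.conditions])
    common = per_run[0].index
    for f in per_run[1:]:
        common = common.intersection(f.index)
    stacked = np.mean([f.loc[common].to_numpy() for f in per_run], axis=0)
    return pd.DataFrame(stacked, index=common)


#: normalized orthogonal polynomial contrast weights over 5 ordered levels
POLY_CONTRASTS_5 = {
    "linear": np.array([-2.0, -1.0, 0.0, 1.0, 2.0]),
    "quadratic": np.array([2.0, -1.0, -2.0, -1.0, 2.0]),
    "cubic": np.array([-1.0, 2.0, 0.0, -2.0, 1.0]),
}


def condition_change(cond_betas: pd.DataFrame, order: str = "cubic") -> np.ndarray:
    """Per-voxel polynomial change coefficient over the 5 sample conditions."""
    w = POLY_CONTRASTS_5[order]
    w = w / (w @ w)
    y = cond_betas.loc[list(SAMPLE_CONDITIONS)].to_numpy()
    return w @ y


def parametric_uncertainty_glm(runs, modulators_by_run) -> np.ndarray:
    """Parametric posterior-variance modulation betas, averaged across runs.

    The per-run design pools all sample events into one onset regressor,
    adds a parametric regressor whose event amplitudes are the mean-centered
    modulator values (model-derived posterior variances), plus estimation
    and gambling nuisance regressors — each convolved with the 3-function
    basis — and a run constant. Returns the canonical modulation beta per
    voxel, combined across runs with an equal-weight contrast.
    """
    betas = []
    for run, modulators in zip(runs, modulators_by_run):
        events = run.events.reset_index(drop=True)
        samples = events[events["trial_type"].isin(SAMPLE_CONDITIONS)]
        modulators = np.asarray(modulators, float)
        if len(samples) != modulators.size:
            raise ValueError(
                f"modulator count {modulators.size} != sample events {len(samples)}"
            )
        centered = modulators - modulators.mean()
        if np.allclose(centered, 0.0):
            raise ValueError("constant modulator: mean-centered regressor is zero")
        cols, names = [], []
        groups = [
            ("samples", samples, np.ones(len(samples))),
            ("uncertainty_mod", samples, centered),
        ]
        for cond in ("estimation", "gamble"):
            sel = events[events["trial_type"] == cond]
            if not sel.empty:
                groups.append((cond, sel, np.ones(len(sel))))
        for name, sel, amp in groups:
            reg = _event_regressors(
                sel["onset"], sel["duration"], amp, run.tr, run.n_scans
            ).sum(axis=1)
            for k, tag in enumerate(BASIS_TAGS):
                cols.append(reg[:, k])
                names.append(name if tag == "canonical" else f"{name}_{tag}")
        cols.append(np.ones(run.n_scans))
        names.append("constant")
        X = np.column_stack(cols)
        coef, *_ = np.linalg.lstsq(X, run.data, rcond=None)
        betas.append(coef[names.index("uncertainty_mod")])
    return np.mean(betas, axis=0)


def split_half_reliability(beta_matrices) -> dict:
    """Across-voxel correlation of SD_BOLD from first- vs second-half trials."""
    pooled = _concat_condition(beta_matrices)
    out = {}
    for cond, bm in pooled.items():
        n = bm.n_trials
        if n < 4:
            raise ValueError("need >= 4 trials for a split-half estimate")
        order = np.argsort(bm.trial_ids)
        half = n // 2
        first = bm.betas[order[:half]].std(axis=0, ddof=1)
        second = bm.betas[order[half:]].std(axis=0, ddof=1)
        out[cond] = float(np.corrcoef(first, second)[0, 1])
    return out


@dataclass
class VariabilityResults:
    """Trial-wise betas, SD_BOLD map, slopes and reliability for one subject."""

    trial_betas: dict
    sd_map: SDBoldMap
    slopes: np.ndarray
    split_half: dict

    def summary(self) -> str:
        lines = ["SD_BOLD variability fit"]
        for cond in self.sd_map.conditions:
            lines.append(
                f"  {cond:<12} n={self.sd_map.n_trials[cond]:<4}"
                f" median SD={np.median(self.sd_map.sd[self.sd_map.conditions.index(cond)]):.4f}"
                f" split-half r={self.split_half.get(cond, float('nan')):.3f}"
            )
        lines.append(f"  median slope over periods: {np.median(self.slopes):.4f}")
        return "\n".join(lines)


class BoldVariabilityModel:
    """LS-S + SD_BOLD pipeline for one subject's runs.

    Parameters
    ----------
    runs : list of BoldRun-like objects (attributes data, events, tr, n_scans).
    conditions : conditions to estimate trial betas for (sample periods).
    """

    def __init__(self, runs, conditions=SAMPLE_CONDITIONS):
        self.runs = list(runs)
        self.conditions = list(conditions)

    def fit(self) -> VariabilityResults:
        mats = [
            bm
            for run in self.runs
            for bm in _run_lss(run, self.conditions).values()
        ]
        sd_map = sd_bold(mats)
        slopes = sdbold_change(sd_map, [c for c in self.conditions])
        return VariabilityResults(
            trial_betas=_concat_condition(mats),
            sd_map=sd_map,
            slopes=slopes,
            split_half=split_half_reliability(mats),
        )
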