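"""Partial least squares (PLS) brain analysis with resampling inference.

Two flavors, both McIntosh-style SVD decompositions:

* **Task PLS** — subject condition-mean brain data are centered on each
  subject's grand mean, averaged over subjects, and the resulting
  condition x voxel matrix is decomposed by SVD. Latent variables (LVs)
  carry condition weights and voxel saliences.
* **Behavioral PLS** — the behavior x voxel cross-correlation matrix
  (columns rank-transformed by default, so relationships are monotone) is
  decomposed by SVD; the first LV's brain and behavior scores give the
  latent brain-behavior correlation.

Significance of each LV's singular value is assessed by permutation
(condition labels shuffled within subject for task PLS; behavior rows
shuffled for behavioral PLS). Voxel robustness is the bootstrap salience
ratio (BSR): the observed salience divided by its bootstrap SE across
subject resamples, thresholded at |BSR| > 3 (~99.9% confidence), with a
minimum cluster extent applied in 3-D.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import ndimage, stats

__all__ = [
    "PLSResults",
    "TaskPLS",
    "BehavioralPLS",
    "task_pls",
    "behavioral_pls",
    "permutation_test",
    "bootstrap_bsr",
    "cluster_threshold",
    "cooks_screen",
    "spatially_matched_latent",
    "latent_regression",
    "polynomial_contrasts",
    "rank_columns",
]

BSR_THRESHOLD = 3.0
MIN_CLUSTER_VOXELS = 25


def rank_columns(x: np.ndarray) -> np.ndarray:
    """Column-wise rank transform (average ranks for ties)."""
    x = np.asarray(x, float)
    if x.ndim == 1:
        return stats.rankdata(x)
    return np.apply_along_axis(stats.rankdata, 0, x)


def _zscore_columns(x: np.ndarray) -> np.ndarray:
    sd = x.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("constant column: cannot standardize")
    return (x - x.mean(axis=0)) / sd


@dataclass
class PLSResults:
    """Latent variables of a PLS decomposition plus resampling inference.

    Saliences are unit-norm per LV; singular values are sorted descending.
    ``brain_scores`` are per-subject projections of the brain data onto the
    saliences ("latent SD_BOLD" when the brain measure is an SD_BOLD map).
    """

    singular_values: np.ndarray
    saliences: np.ndarray  # (n_voxels, n_lv)
    weights: np.ndarray  # condition or behavior weights, (n_items, n_lv)
    brain_scores: np.ndarray
    mode: str
    perm_p: np.ndarray | None = None
    n_perm: int = 0
    bsr: np.ndarray | None = None
    n_boot: int = 0
    latent_correlation: float | None = None
    design_scores: np.ndarray | None = None
    extras: dict = field(default_factory=dict)

    @property
    def explained(self) -> np.ndarray:
        s2 = self.singular_values**2
        return s2 / s2.sum()

    def summary(self) -> str:
        lines = [f"{self.mode} PLS: {self.singular_values.size} latent variable(s)"]
        for k, sv in enumerate(self.singular_values):
            p = "" if self.perm_p is None else f"  perm p={self.perm_p[k]:.4g}"
            lines.append(
                f"  LV{k + 1}: singular value {sv:.4f}"
                f" ({100 * self.explained[k]:.1f}% crossblock var){p}"
            )
        if self.latent_correlation is not None:
            lines.append(f"  latent correlation (LV1): {self.latent_correlation:.3f}")
        if self.bsr is not None:
            n_rob = int((np.abs(self.bsr[:, 0]) > BSR_THRESHOLD).sum())
            lines.append(
                f"  robust voxels on LV1 (|BSR| > {BSR_THRESHOLD:g}): {n_rob}"
                f" of {self.bsr.shape[0]} ({self.n_boot} bootstraps)"
            )
        return "\n".join(lines)


def _svd(mat: np.ndarray):
    u, s, vt = np.linalg.svd(mat, full_matrices=False)
    return u, s, vt.T  # saliences as columns of v


class TaskPLS:
    """Mean-centered task PLS of subject x condition x voxel brain data."""

    def __init__(self, brain: np.ndarray):
        brain = np.asarray(brain, float)
        if brain.ndim != 3:
            raise ValueError("brain must be subject x condition x voxel")
        if brain.shape[1] < 2:
            raise ValueError("task PLS needs at least 2 conditions")
        if brain.shape[0] < 3:
            raise ValueError("task PLS needs at least 3 subjects")
        self.brain = brain

    def _crossblock(self, brain: np.ndarray) -> np.ndarray:
        centered = brain - brain.mean(axis=1, keepdims=True)
        return centered.mean(axis=0)  # condition x voxel

    def fit(self, n_perm: int = 0, n_boot: int = 0, seed=None) -> PLSResults:
        rng = np.random.default_rng(seed)
        mat = self._crossblock(self.brain)
        u, s, v = _svd(mat)
        scores = np.einsum("scv,vk->sck", self.brain, v)
        res = PLSResults(
            singular_values=s,
            saliences=v,
            weights=u,
            brain_scores=scores,
            mode="task",
        )
        if n_perm:
            perm_s = np.empty((n_perm, s.size))
            for b in range(n_perm):
                shuffled = np.stack(
                    [subj[rng.permutation(subj.shape[0])] for subj in self.brain]
                )
                perm_s[b] = np.linalg.svd(
                    self._crossblock(shuffled), compute_uv=False
                )[: s.size]
            res.perm_p = (1.0 + (perm_s >= s).sum(axis=0)) / (n_perm + 1.0)
            res.n_perm = n_perm
        if n_boot:
            res.bsr = _bootstrap(
                self.brain, v, s, rng, n_boot, self._crossblock
            )
            res.n_boot = n_boot
        return res


class BehavioralPLS:
    """Behavioral PLS of subject x voxel brain data vs subject behavior."""

    def __init__(self, brain: np.ndarray, behavior: np.ndarray, rank: bool = True):
        brain = np.asarray(brain, float)
        behavior = np.asarray(behavior, float)
        if behavior.ndim == 1:
            behavior = behavior[:, None]
        if brain.shape[0] != behavior.shape[0]:
            raise ValueError("brain and behavior must share the subject axis")
        if brain.shape[0] < 4:
            raise ValueError("behavioral PLS needs at least 4 subjects")
        if not np.all(np.isfinite(behavior)):
            raise ValueError("behavior must be finite")
        if np.any(behavior.std(axis=0) == 0):
            raise ValueError("constant behavior column")
        self.rank = rank
        self.brain = rank_columns(brain) if rank else brain
        self.behavior = rank_columns(behavior) if rank else behavior

    @staticmethod
    def _crossblock(brain: np.ndarray, behavior: np.ndarray) -> np.ndarray:
        zb = _zscore_columns(behavior)
        zx = _zscore_columns(brain)
        return zb.T @ zx / (brain.shape[0] - 1)  # behavior x voxel correlations

    def fit(self, n_perm: int = 0, n_boot: int = 0, seed=None) -> PLSResults:
        rng = np.random.default_rng(seed)
        mat = self._crossblock(self.brain, self.behavior)
        u, s, v = _svd(mat)
        brain_scores = self.brain @ v
        design_scores = self.behavior @ u
        lv1 = float(np.corrcoef(brain_scores[:, 0], design_scores[:, 0])[0, 1])
        res = PLSResults(
            singular_values=s,
            saliences=v,
            weights=u,
            brain_scores=brain_scores,
            design_scores=design_scores,
            latent_correlation=lv1,
            mode="behavioral",
        )
        if n_perm:
            perm_s = np.empty((n_perm, s.size))
            for b in range(n_perm):
                perm = rng.permutation(self.behavior.shape[0])
                perm_s[b] = np.linalg.svd(
                    self._crossblock(self.brain, self.behavior[perm]),
                    compute_uv=False,
                )[: s.size]
            res.perm_p = (1.0 + (perm_s >= s).sum(axis=0)) / (n_perm + 1.0)
            res.n_perm = n_perm
        if n_boot:
            res.bsr = _bootstrap_behavioral(
                self.brain, self.behavior, v, rng, n_boot
            )
            res.n_boot = n_boot
        return res


def _bootstrap(brain, v, s, rng, n_boot, crossblock):
    n_sub = brain.shape[0]
    samples = np.empty((n_boot,) + v.shape)
    n_degenerate = 0
    for b in range(n_boot):
        take = rng.integers(0, n_sub, size=n_sub)
        if np.unique(take).size == 1:
            n_degenerate += 1
        _, _, vb = _svd(crossblock(brain[take]))
        sign = np.sign(np.einsum("vk,vk->k", vb, v))
        sign[sign == 0] = 1.0
        samples[b] = vb * sign
    if n_degenerate:
        warnings.warn(f"{n_degenerate} degenerate bootstrap resamples")
    se = samples.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        return v / se


def _bootstrap_behavioral(brain, behavior, v, rng, n_boot):
    n_sub = brain.shape[0]
    samples = np.empty((n_boot,) + v.shape)
    n_degenerate = 0
    for b in range(n_boot):
        take = rng.integers(0, n_sub, size=n_sub)
        sub_beh = behavior[take]
        if np.any(sub_beh.std(axis=0) == 0) or np.unique(take).size == 1:
            n_degenerate += 1
            samples[b] = v
            continue
        _, _, vb = _svd(BehavioralPLS._crossblock(brain[take], sub_beh))
        sign = np.sign(np.einsum("vk,vk->k", vb, v))
        sign[sign == 0] = 1.0
        samples[b] = vb * sign
    if n_degenerate:
        warnings.warn(f"{n_degenerate} degenerate bootstrap resamples")
    se = samples.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        return v / se


def task_pls(brain, n_perm: int = 0, n_boot: int = 0, seed=None) -> PLSResults:
    """Functional wrapper around :class:`TaskPLS`."""
    return TaskPLS(brain).fit(n_perm=n_perm, n_boot=n_boot, seed=seed)


def behavioral_pls(
    brain, behavior, rank: bool = True, n_perm: int = 0, n_boot: int = 0, seed=None
) -> PLSResults:
    """Functional wrapper around :class:`BehavioralPLS`."""
    return BehavioralPLS(brain, behavior, rank=rank).fit(
        n_perm=n_perm, n_boot=n_boot, seed=seed
    )


def permutation_test(model, n_perm: int = 1000, seed=None) -> np.ndarray:
    """Permutation p per LV for a TaskPLS or BehavioralPLS model."""
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    return model.fit(n_perm=n_perm, seed=seed).perm_p


def bootstrap_bsr(model, n_boot: int = 1000, seed=None) -> np.ndarray:
    """Bootstrap salience ratios (voxels x LVs) for a PLS model."""
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    return model.fit(n_boot=n_boot, seed=seed).bsr


def cluster_threshold(
    mask_volume: np.ndarray,
    min_size: int = MIN_CLUSTER_VOXELS,
    bsr_volume: np.ndarray | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Remove connected components smaller than ``min_size`` (6-connectivity).

    Returns the pruned boolean volume and a cluster table with size, peak
    coordinate and peak |BSR| (when a BSR volume is supplied).
    """
    structure = ndimage.generate_binary_structure(3, 1)  # faces only
    labeled, n = ndimage.label(np.asarray(mask_volume, bool), structure=structure)
    pruned = np.zeros_like(mask_volume, dtype=bool)
    rows = []
    for lab in range(1, n + 1):
        comp = labeled == lab
        size = int(comp.sum())
        if size < min_size:
            continue
        pruned |= comp
        if bsr_volume is not None:
            vals = np.where(comp, np.abs(bsr_volume), -np.inf)
            peak = np.unravel_index(np.argmax(vals), vals.shape)
            peak_bsr = float(bsr_volume[peak])
        else:
            coords = np.argwhere(comp)
            peak = tuple(coords[0])
            peak_bsr = np.nan
        rows.append(
            {"size": size, "peak_x": peak[0], "peak_y": peak[1], "peak_z": peak[2], "peak_bsr": peak_bsr}
        )
    table = pd.DataFrame(rows, columns=["size", "peak_x", "peak_y", "peak_z", "peak_bsr"])
    return pruned, table


def cooks_screen(X, y, threshold_factor: float = 4.0) -> np.ndarray:
    """Indices of multivariate outliers with Cook's distance > factor / n."""
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    if n <= X.shape[1] + 1:
        raise ValueError("need n > k + 1 observations")
    model = sm.OLS(np.asarray(y, float), sm.add_constant(X)).fit()
    if model.ssr <= 1e-12 * max(1.0, float(np.sum(np.square(y)))):
        return np.array([], dtype=int)  # exact fit: all distances are zero
    d = model.get_influence().cooks_distance[0]
    return np.flatnonzero(d > threshold_factor / n)


def spatially_matched_latent(saliences: np.ndarray, measure: np.ndarray) -> np.ndarray:
    """Project a second voxel-wise measure onto an existing LV's saliences.

    Yields per-subject scores of measure B in the spatial pattern of
    analysis A — a latent control variable for regression models.
    """
    saliences = np.asarray(saliences, float)
    measure = np.asarray(measure, float)
    if measure.shape[-1] != saliences.shape[0]:
        raise ValueError("voxel spaces differ")
    return measure @ saliences


def _semi_partial_eta2(X, y, names):
    """Per-predictor t, p and semi-partial eta^2 (SS entered last / SS total)."""
    Xc = sm.add_constant(X)
    full = sm.OLS(y, Xc).fit()
    ss_total = float(np.sum((y - y.mean()) ** 2))
    rows = []
    for j, name in enumerate(names):
        keep = [0] + [1 + k for k in range(len(names)) if k != j]
        reduced = sm.OLS(y, Xc[:, keep]).fit()
        rows.append(
            {
                "predictor": name,
                "coef": float(full.params[1 + j]),
                "t": float(full.tvalues[1 + j]),
                "p": float(full.pvalues[1 + j]),
                "semi_partial_eta2": float((reduced.ssr - full.ssr) / ss_total),
            }
        )
    return full, pd.DataFrame(rows)


def latent_regression(y, X: pd.DataFrame, rank: bool = True) -> dict:
    """Least-squares regression of an outcome on latent scores / parameters.

    Variables are rank-transformed when ``rank`` (monotone relationships,
    robust to univariate outliers). Returns overall F, p and R^2 plus
    per-predictor t, p and semi-partial eta^2.
    """
    X = pd.DataFrame(X)
    names = list(X.columns)
    y = np.asarray(y, float)
    Xv = X.to_numpy(float)
    if rank:
        y = rank_columns(y)
        Xv = rank_columns(Xv)
    if np.linalg.cond(sm.add_constant(Xv)) > 1e8:
        warnings.warn("ill-conditioned design (collinearity)")
    full, table = _semi_partial_eta2(Xv, y, names)
    return {
        "F": float(full.fvalue),
        "p": float(full.f_pvalue),
        "r_squared": float(full.rsquared),
        "df": (int(full.df_model), int(full.df_resid)),
        "predictors": table,
    }


#: orthogonal polynomial contrast weights over 5 ordered conditions
POLY_WEIGHTS = {
    "linear": np.array([-2.0, -1.0, 0.0, 1.0, 2.0]),
    "quadratic": np.array([2.0, -1.0, -2.0, -1.0, 2.0]),
    "cubic": np.array([-1.0, 2.0, 0.0, -2.0, 1.0]),
}


def polynomial_contrasts(scores: np.ndarray) -> pd.DataFrame:
    """Orthogonal polynomial trend tests on subject x 5-condition scores.

    Fits the long-form model score ~ linear + quadratic + cubic + subject
    indicators and reports F, p and semi-partial eta^2 per polynomial order.
    """
    scores = np.asarray(scores, float)
    n_sub, n_cond = scores.shape
    if n_cond != 5:
        raise ValueError("expect exactly 5 ordered conditions")
    y = scores.ravel()
    subj = np.repeat(np.arange(n_sub), n_cond)
    poly = np.column_stack(
        [np.tile(POLY_WEIGHTS[k] / np.linalg.norm(POLY_WEIGHTS[k]), n_sub) for k in POLY_WEIGHTS]
    )
    dummies = pd.get_dummies(subj, drop_first=True).to_numpy(float)
    X = np.hstack([poly, dummies])
    Xc = sm.add_constant(X)
    full = sm.OLS(y, Xc).fit()
    ss_total = float(np.sum((y - y.mean()) ** 2))
    mse = full.ssr / full.df_resid
    rows = []
    for j, name in enumerate(POLY_WEIGHTS):
        keep = [k for k in range(Xc.shape[1]) if k != 1 + j]
        reduced = sm.OLS(y, Xc[:, keep]).fit()
        ss_term = float(reduced.ssr - full.ssr)
        f_stat = ss_term / mse
        rows.append(
            {
                "order": name,
                "F": f_stat,
                "p": float(stats.f.sf(f_stat, 1, full.df_resid)),
                "semi_partial_eta2": ss_term / ss_total,
            }
        )
    return pd.DataFrame(rows)
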