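"""Behavioral outcome measures for the marble task.

Estimation error on a trial is the absolute difference between the reported
blue-marble proportion and the proportion actually experienced in that
trial's samples. The "extreme jar bias" is a subject's regression slope of
trial-wise error on the jar's marble-ratio distance from 50:50; a positive
slope means extreme jars are misestimated toward 0.5 (under-extremity).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

__all__ = [
    "estimation_error",
    "trial_errors",
    "subject_median_error",
    "extreme_jar_bias",
    "trialwise_bias_test",
    "winsorize",
    "subject_summary",
]


def estimation_error(trial, experienced_method: str = "pooled") -> float:
    """Absolute estimation error for one trial (NaN if no valid response)."""
    if not trial.valid:
        return float("nan")
    return abs(trial.experienced_proportion(experienced_method) - trial.reported_estimate)


def trial_errors(trials, experienced_method: str = "pooled") -> np.ndarray:
    """Errors for all valid trials, in trial order."""
    return np.array(
        [estimation_error(t, experienced_method) for t in trials if t.valid]
    )


def subject_median_error(trials, experienced_method: str = "pooled") -> float:
    errs = trial_errors(trials, experienced_method)
    if errs.size == 0:
        raise ValueError("no valid trials")
    return float(np.median(errs))


def extreme_jar_bias(trials, experienced_method: str = "pooled") -> float:
    """Unstandardized slope of trial error on |jar p_blue - 0.5|."""
    valid = [t for t in trials if t.valid]
    dist = np.array([abs(t.jar_p_blue - 0.5) for t in valid])
    if np.unique(dist).size < 3:
        raise ValueError("need at least 3 distinct jar distances")
    errs = trial_errors(valid, experienced_method)
    slope = np.polyfit(dist, errs, 1)[0]
    return float(slope)


def trialwise_bias_test(df: pd.DataFrame) -> dict:
    """Group-level test of the extreme-jar bias with subject covariate.

    Fits trial-wise error on jar distance plus subject indicator variables
    and returns the distance term's F, p, and semi-partial eta^2
    (SS of distance entered last over total SS).

    Parameters
    ----------
    df : DataFrame with columns ``error``, ``distance``, ``subject``.
    """
    if df["subject"].nunique() < 1:
        raise ValueError("need at least one subject")
    if df["subject"].nunique() == 1:
        full = smf.ols("error ~ distance", data=df).fit()
        reduced = smf.ols("error ~ 1", data=df).fit()
    else:
        full = smf.ols("error ~ distance + C(subject)", data=df).fit()
        reduced = smf.ols("error ~ C(subject)", data=df).fit()
    ss_total = float(np.sum((df["error"] - df["error"].mean()) ** 2))
    ss_distance = float(reduced.ssr - full.ssr)
    f_stat = ss_distance / (full.ssr / full.df_resid)
    p = float(stats.f.sf(f_stat, 1, full.df_resid))
    return {
        "F": float(f_stat),
        "df": (1, int(full.df_resid)),
        "p": p,
        "semi_partial_eta2": ss_distance / ss_total,
        "slope": float(full.params["distance"]),
    }


def winsorize(values) -> np.ndarray:
    """Tukey-fence winsorization used for all subject-level measures.

    Points beyond 1.5 IQR from the quartiles are replaced by the most
    extreme value among the non-outlying points. Idempotent.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 values")
    q25, q75 = np.percentile(x, [25, 75])
    iqr = q75 - q25
    lo_fence, hi_fence = q25 - 1.5 * iqr, q75 + 1.5 * iqr
    inside = x[(x >= lo_fence) & (x <= hi_fence)]
    out = x.copy()
    out[x < lo_fence] = inside.min()
    out[x > hi_fence] = inside.max()
    return out


def subject_summary(datasets, winsorize_measures: bool = True) -> pd.DataFrame:
    """Per-subject median error and extreme-jar bias for a group.

    Parameters
    ----------
    datasets : list of per-subject trial lists.
    """
    rows = [
        {
            "subject": i,
            "median_error": subject_median_error(trials),
            "extreme_jar_bias": extreme_jar_bias(trials),
        }
        for i, trials in enumerate(datasets)
    ]
    df = pd.DataFrame(rows)
    if winsorize_measures and len(df) >= 4:
        for col in ("median_error", "extreme_jar_bias"):
            df[col + "_winsorized"] = winsorize(df[col].to_numpy())
    return df
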