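"""ENGAGE behavioral analytics.

Outcome classification from lick times, hit-rate psychometrics, modulation
indices, the coupling of pre-trial ACCp activity with error rates
(quantile curves), miss-streak structure, within-session outcome time
courses, and the explorer/exploiter strategy split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from engage.stats import LinregResult, simple_linreg


def classify_outcomes(trials: pd.DataFrame,
                      response_window: float = 1.5) -> pd.DataFrame:
    """Label each trial impulsive / hit / miss from its first lick time.

    ``lick_s`` is the first-lick time relative to trial onset (NaN when the
    mouse never licked); ``delay_s`` is the No-Go→Go delay. A lick strictly
    inside the delay period is an impulsive error (terminating the trial);
    a lick in the response window after the Go cue is a hit — a lick
    exactly at cue onset counts as post-cue (closed-left convention);
    anything else is a miss. RT is measured from the Go cue on hits and
    from trial onset on impulsive errors.
    """
    for col in ("delay_s", "lick_s"):
        if col not in trials.columns:
            raise ValueError(f"trial table lacks column {col!r}")
    lick = trials["lick_s"].to_numpy(dtype=float)
    delay = trials["delay_s"].to_numpy(dtype=float)
    licked = np.isfinite(lick)
    impulsive = licked & (lick > 0) & (lick < delay)
    hit = licked & ~impulsive & (lick >= delay) & \
        (lick <= delay + response_window)
    outcome = np.where(impulsive, "impulsive", np.where(hit, "hit", "miss"))
    rt = np.where(impulsive, lick, np.where(hit, lick - delay, np.nan))
    out = trials.copy()
    out["outcome"] = outcome
    out["rt_s"] = rt
    return out


def hit_rate_psychometrics(trials: pd.DataFrame,
                           by: tuple[str, ...] = ("intensity", "cloud", "aid")
                           ) -> pd.DataFrame:
    """Hit rate per stimulus cell, with per-cell trial counts.

    Impulsive-terminated trials are excluded from the denominator — the Go
    cue was never delivered on those trials — so the rate is
    hits / (hits + misses). Empty cells yield NaN.
    """
    go = trials[trials["outcome"] != "impulsive"]
    grouped = go.groupby(list(by), observed=True)["outcome"]
    table = grouped.agg(
        hit_rate=lambda s: (s == "hit").mean(),
        n="size").reset_index()
    return table


def modulation_index(rate_a: float, rate_b: float) -> float:
    """Difference of two rates normalized by their sum, in [−1, 1].

    Returns NaN (flagged missing) when both rates are zero.
    """
    if rate_a < 0 or rate_b < 0:
        raise ValueError("rates must be nonnegative")
    total = rate_a + rate_b
    if total == 0:
        return np.nan
    return (rate_a - rate_b) / total


def strategy_features(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-mouse strategy features from a multi-mouse trial table.

    ``impulsive_rate`` is the fraction of impulsive trials; ``cloud_mi``
    the modulation index of hit rate without vs. with the tone cloud (high
    = cloud hurts detection); ``visual_mi`` the index of aided vs. unaided
    hit rate.
    """

    def per_mouse(df: pd.DataFrame) -> pd.Series:
        go = df[df["outcome"] != "impulsive"]
        hr = go.groupby("cloud", observed=True)["outcome"] \
            .apply(lambda s: (s == "hit").mean())
        ha = go.groupby("aid", observed=True)["outcome"] \
            .apply(lambda s: (s == "hit").mean())
        return pd.Series({
            "impulsive_rate": (df["outcome"] == "impulsive").mean(),
            "cloud_mi": modulation_index(hr.get(False, np.nan),
                                         hr.get(True, np.nan)),
            "visual_mi": modulation_index(ha.get(True, np.nan),
                                          ha.get(False, np.nan)),
        })

    return trials.groupby("mouse").apply(per_mouse, include_groups=False)


@dataclass
class QuantileCurve:
    """Error rate vs. pre-trial-activity quantile, with its regression."""

    table: pd.DataFrame       # mouse, bin, mean_pretrial, norm_rate
    regression: LinregResult
    n_quantiles: int
    error_type: str


def quantile_error_curve(trials: pd.DataFrame, error_type: str = "impulsive",
                         n_quantiles: int = 10,
                         x_axis: str = "bin") -> QuantileCurve:
    """Normalized error rate as a function of pre-trial activity quantile.

    Pre-trial activity (column ``pretrial``) is binned into per-mouse
    quantiles; the error rate per bin is divided by that mouse's overall
    rate of the given error type; bins are then pooled across mice into a
    simple linear regression of normalized rate on bin index (or on the
    bin-mean activity with ``x_axis="pretrial"``). Mice without any error
    of the given type are dropped with a warning.
    """
    if len(trials) < n_quantiles * 5:
        raise ValueError("too few trials for a stable quantile curve")
    if "mouse" not in trials.columns:
        trials = trials.assign(mouse=0)
    rows = []
    for mouse, df in trials.groupby("mouse"):
        overall = (df["outcome"] == error_type).mean()
        if overall == 0:
            warnings.warn(f"mouse {mouse!r} has no {error_type} trials; dropped")
            continue
        ranks = df["pretrial"].rank(method="first")
        bins = pd.qcut(ranks, n_quantiles, labels=False)
        for b in range(n_quantiles):
            sel = df[bins == b]
            rows.append({
                "mouse": mouse, "bin": b + 1,
                "mean_pretrial": sel["pretrial"].mean(),
                "norm_rate": (sel["outcome"] == error_type).mean() / overall,
            })
    table = pd.DataFrame(rows)
    if table.empty:
        raise ValueError(f"no mouse contributed {error_type} trials")
    x = table["bin" if x_axis == "bin" else "mean_pretrial"].to_numpy(float)
    reg = simple_linreg(x, table["norm_rate"].to_numpy(float))
    return QuantileCurve(table=table, regression=reg,
                         n_quantiles=n_quantiles, error_type=error_type)


def strategy_classify(features: pd.DataFrame, seed: int = 0) -> pd.Series:
    """Two-group strategy split on the (impulsive rate, cloud MI) plane.

    2-means clustering on the standardized features with 100 restarts;
    the cluster with the higher mean impulsive rate is labeled
    ``explorer``, the other ``exploiter``. Deterministic given the seed and
    invariant to the ordering of mice.
    """
    cols = ["impulsive_rate", "cloud_mi"]
    X = features[cols].to_numpy(dtype=float)
    if len(X) < 4:
        raise ValueError("need at least 4 mice to split strategies")
    sd = X.std(axis=0)
    if np.any(sd == 0) and np.all(X == X[0]):
        raise ValueError("all mice identical; no strategy structure")
    Xs = (X - X.mean(axis=0)) / np.where(sd == 0, 1.0, sd)
    km = KMeans(n_clusters=2, n_init=100, random_state=seed).fit(Xs)
    explorer_cluster = int(np.argmax(
        [features["impulsive_rate"].to_numpy()[km.labels_ == k].mean()
         for k in (0, 1)]))
    labels = np.where(km.labels_ == explorer_cluster, "explorer", "exploiter")
    return pd.Series(labels, index=features.index, name="strategy")


def miss_streaks(outcomes) -> np.ndarray:
    """Lengths of runs of consecutive miss trials, in trial order."""
    miss = np.asarray(outcomes) == "miss"
    if not miss.any():
        return np.array([], dtype=int)
    change = np.flatnonzero(np.diff(miss.astype(int)))
    starts = np.concatenate([[0], change + 1])
    ends = np.concatenate([change + 1, [miss.size]])
    return np.array([e - s for s, e in zip(starts, ends) if miss[s]])


def streak_summary(outcomes) -> dict:
    """Max and mean miss-streak length (0 when there are no misses)."""
    streaks = miss_streaks(outcomes)
    if streaks.size == 0:
        return {"max": 0, "mean": 0.0, "n_streaks": 0}
    return {"max": int(streaks.max()), "mean": float(streaks.mean()),
            "n_streaks": int(streaks.size)}


def outcome_timecourse(outcomes, n_bins: int = 2) -> pd.DataFrame:
    """Outcome proportions per within-session time bin (rows sum to 1)."""
    outcomes = np.asarray(outcomes)
    if outcomes.size < n_bins:
        raise ValueError("session shorter than the number of bins")
    edges = np.linspace(0, outcomes.size, n_bins + 1).astype(int)
    rows = []
    for k in range(n_bins):
        seg = outcomes[edges[k]:edges[k + 1]]
        rows.append({o: float(np.mean(seg == o))
                     for o in ("impulsive", "hit", "miss")})
    return pd.DataFrame(rows, index=pd.RangeIndex(n_bins, name="bin"))
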