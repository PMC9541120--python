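"""Per-product gaze/pupil variables, rank scores, paired tests and AUCs.

Six independent variables are computed per trial x product:

* ``total_dwell_time`` — sum of the product's dwell durations (s);
* ``median_dwell_duration`` — median of its individual dwell durations (s);
* ``n_dwells`` — number of dwells;
* ``mean_pupil`` — mean raw pupil diameter over samples inside its dwells (mm);
* ``mean_pupil_minus_baseline`` — the same mean relative to the trial's
  phase-scrambled baseline (mm);
* ``mean_detrended_pupil`` — the same mean on the detrended signal (mm).

A product that was never dwelled on gets 0 for the gaze variables and
missing (NaN) for the pupil variables — no viewing, no pupil sample.

Discrimination between preferred (chosen) and nonpreferred products is
summarised two ways: paired t-tests on participant-level means, and the
ROC AUC, i.e. the Mann-Whitney probability that a random preferred value
exceeds a random nonpreferred one (ties counted half).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dwell_extraction import Dwell, dwell_sample_indices
from .io_formats import N_PRODUCTS

GAZE_VARIABLES = ("total_dwell_time", "median_dwell_duration", "n_dwells")
PUPIL_VARIABLES = ("mean_pupil", "mean_pupil_minus_baseline", "mean_detrended_pupil")
VARIABLES = GAZE_VARIABLES + PUPIL_VARIABLES


def compute_features(
    dwells: Sequence[Dwell],
    pupil_raw: np.ndarray,
    pupil_detrended: np.ndarray,
    baseline: float,
    chosen: int,
    trial_id: int,
    n_products: int = N_PRODUCTS,
) -> pd.DataFrame:
    """Six variables per product for one trial.

    ``pupil_raw`` / ``pupil_detrended`` are the trial's stimulus-phase pupil
    samples, index-aligned with the label sequence the dwells came from.
    """
    pupil_raw = np.asarray(pupil_raw, dtype=float)
    pupil_detrended = np.asarray(pupil_detrended, dtype=float)
    rows = []
    for product in range(1, n_products + 1):
        own = [d for d in dwells if d.product_id == product]
        if own:
            durations = np.array([d.duration for d in own])
            idx = dwell_sample_indices(own)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
                mean_raw = float(np.nanmean(pupil_raw[idx]))
                mean_det = float(np.nanmean(pupil_detrended[idx]))
            row = {
                "total_dwell_time": float(durations.sum()),
                "median_dwell_duration": float(np.median(durations)),
                "n_dwells": len(own),
                "mean_pupil": mean_raw,
                "mean_pupil_minus_baseline": mean_raw - baseline,
                "mean_detrended_pupil": mean_det,
            }
        else:
            row = {
                "total_dwell_time": 0.0,
                "median_dwell_duration": 0.0,
                "n_dwells": 0,
                "mean_pupil": np.nan,
                "mean_pupil_minus_baseline": np.nan,
                "mean_detrended_pupil": np.nan,
            }
        row["trial_id"] = trial_id
        row["product_id"] = product
        row["chosen"] = product == chosen
        rows.append(row)
    cols = ["trial_id", "product_id", *VARIABLES, "chosen"]
    return pd.DataFrame(rows)[cols]


def rank_products(values: Sequence[float], product_ids: Sequence[int] | None = None) -> np.ndarray:
    """Rank products 1 (highest value) to n (lowest).

    Ties are broken by ascending product id; missing values rank below every
    observed value (then also by product id).
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    ids = np.arange(1, n + 1) if product_ids is None else np.asarray(product_ids)
    keyed = np.where(np.isfinite(values), values, -np.inf)
    order = np.lexsort((ids, -keyed))
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(1, n + 1)
    return ranks


def rank_table(features: pd.DataFrame, variables: Sequence[str] = VARIABLES) -> pd.DataFrame:
    """Long-form rank scores per participant x trial x variable x product."""
    group_cols = [c for c in ("participant_id", "trial_id") if c in features.columns]
    out = []
    for keys, grp in features.groupby(group_cols, sort=True):
        if not isinstance(keys, tuple):
            keys = (keys,)
        grp = grp.sort_values("product_id")
        for var in variables:
            ranks = rank_products(grp[var].to_numpy(), grp["product_id"].to_numpy())
            block = pd.DataFrame(
                {
                    "product_id": grp["product_id"].to_numpy(),
                    "variable": var,
                    "rank": ranks,
                    "chosen": grp["chosen"].to_numpy(),
                }
            )
            for col, key in zip(group_cols, keys):
                block[col] = key
            out.append(block)
    return pd.concat(out, ignore_index=True)


def rank_choice_distribution(
    features: pd.DataFrame, variables: Sequence[str] = VARIABLES
) -> pd.DataFrame:
    """Percent of trials in which the chosen product held each rank.

    Returns a frame indexed by rank 1-5 with one column per variable; each
    column sums to 100.
    """
    ranks = rank_table(features, variables)
    chosen = ranks[ranks["chosen"]]
    out = {}
    for var in variables:
        r = chosen.loc[chosen["variable"] == var, "rank"]
        counts = r.value_counts().reindex(range(1, N_PRODUCTS + 1), fill_value=0)
        out[var] = 100.0 * counts / len(r)
    df = pd.DataFrame(out)
    df.index.name = "rank"
    return df


@dataclass(frozen=True)
class PairedTResult:
    t: float
    df: int
    p: float
    mean_diff: float
    sd_diff: float


def paired_comparison(preferred: Sequence[float], nonpreferred: Sequence[float]) -> PairedTResult:
    """Paired t-test on per-participant preferred vs nonpreferred means."""
    a = np.asarray(preferred, dtype=float)
    b = np.asarray(nonpreferred, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    keep = np.isfinite(a) & np.isfinite(b)
    a, b = a[keep], b[keep]
    n = len(a)
    if n < 2:
        raise ValueError("need at least two complete pairs")
    diff = a - b
    sd = float(diff.std(ddof=1))
    mean = float(diff.mean())
    if sd == 0.0:
        warnings.warn("zero variance of paired differences; p degenerate")
        if mean == 0.0:
            return PairedTResult(t=0.0, df=n - 1, p=1.0, mean_diff=0.0, sd_diff=0.0)
        t = np.inf if mean > 0 else -np.inf
        return PairedTResult(t=t, df=n - 1, p=0.0, mean_diff=mean, sd_diff=0.0)
    res = stats.ttest_rel(a, b)
    return PairedTResult(
        t=float(res.statistic), df=n - 1, p=float(res.pvalue), mean_diff=mean, sd_diff=sd
    )


def roc_auc(preferred: Sequence[float], nonpreferred: Sequence[float]) -> float:
    """P(preferred > nonpreferred) + 0.5 P(tie) over all cross pairs.

    Computed via midranks (the Mann-Whitney U statistic), equivalent to
    brute-force enumeration of all pairs.
    """
    pos = np.asarray(preferred, dtype=float)
    neg = np.asarray(nonpreferred, dtype=float)
    pos = pos[np.isfinite(pos)]
    neg = neg[np.isfinite(neg)]
    if not len(pos) or not len(neg):
        raise ValueError("both value vectors must be non-empty")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u = ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2
    return float(u / (len(pos) * len(neg)))


def participant_summary(
    features: pd.DataFrame, variables: Sequence[str] = VARIABLES
) -> pd.DataFrame:
    """Participant-level preferred/nonpreferred means and AUC per variable.

    The preferred mean is the across-trial mean of the chosen product's
    value; the nonpreferred mean averages the four non-chosen products
    within trial, then across trials.  The AUC pools the participant's
    trial x product values (chosen vs not); missing pupil values from
    never-visited products are excluded.
    """
    rows = []
    for pid, grp in features.groupby("participant_id", sort=True):
        pref = grp[grp["chosen"]]
        nonpref = grp[~grp["chosen"]]
        for var in variables:
            p = pref[var].to_numpy(dtype=float)
            q = nonpref.groupby("trial_id")[var].mean().to_numpy(dtype=float)
            rows.append(
                {
                    "participant_id": pid,
                    "variable": var,
                    "preferred_mean": float(np.nanmean(p)),
                    "nonpreferred_mean": float(np.nanmean(q)),
                    "auc": roc_auc(p, nonpref[var].to_numpy(dtype=float)),
                }
            )
    return pd.DataFrame(rows)


def table_one(
    features: pd.DataFrame,
    variables: Sequence[str] = VARIABLES,
    pooling: str = "per_participant",
) -> pd.DataFrame:
    """Preferred/nonpreferred summary per variable: M, SD, paired t, AUC.

    ``pooling='per_participant'`` (default) computes one AUC per participant
    and averages; ``'pooled'`` computes a single AUC over all trial x product
    values of all participants.
    """
    summ = participant_summary(features, variables)
    rows = []
    for var in variables:
        sv = summ[summ["variable"] == var]
        res = paired_comparison(sv["preferred_mean"], sv["nonpreferred_mean"])
        if pooling == "per_participant":
            auc = float(sv["auc"].mean())
        elif pooling == "pooled":
            auc = roc_auc(
                features.loc[features["chosen"], var].to_numpy(dtype=float),
                features.loc[~features["chosen"], var].to_numpy(dtype=float),
            )
        else:
            raise ValueError(f"unknown pooling '{pooling}'")
        rows.append(
            {
                "variable": var,
                "preferred_mean": float(sv["preferred_mean"].mean()),
                "preferred_sd": float(sv["preferred_mean"].std(ddof=1)),
                "nonpreferred_mean": float(sv["nonpreferred_mean"].mean()),
                "nonpreferred_sd": float(sv["nonpreferred_mean"].std(ddof=1)),
                "t": res.t,
                "df": res.df,
                "p": res.p,
                "auc": auc,
            }
        )
    return pd.DataFrame(rows).set_index("variable")


def event_locked_pupil(
    d: np.ndarray,
    t: np.ndarray,
    fs: float,
    onsets: Sequence[float],
    window: float,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Average pupil segments time-locked to dwell onsets.

    Returns ``(lags, trace, n_used)`` where ``lags`` are seconds relative to
    onset and ``trace`` is the across-onset mean (NaN-aware).  Segments that
    would run past the end of the series are dropped.
    """
    d = np.asarray(d, dtype=float)
    t = np.asarray(t, dtype=float)
    n_win = int(round(window * fs))
    lags = np.arange(n_win) / fs
    segments = []
    for onset in onsets:
        start = int(np.searchsorted(t, onset))
        if start + n_win > len(d):
            continue
        segments.append(d[start : start + n_win])
    if not segments:
        return lags, np.full(n_win, np.nan), 0
    stacked = np.vstack(segments)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        trace = np.nanmean(stacked, axis=0)
    return lags, trace, len(segments)
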