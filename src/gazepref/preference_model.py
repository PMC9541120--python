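"""Per-participant ordinal preference models and model comparison.

For each participant, a cumulative-link (ordered-logit) model is fitted by
maximum likelihood over the participant's trial x product observations.
The ordered outcome has two categories, 1 = chosen < 2 = not chosen; with
two categories the cumulative-link model is equivalent to binary logistic
regression up to sign, and under this coding a product variable that makes
choice *more* likely receives a *negative* coefficient.

Three nested predictor sets are compared:

* ``dwell_only`` — total dwell time;
* ``all_gaze`` — plus median dwell duration and number of dwells;
* ``gaze_plus_pupil`` — plus the three pupil variables.

Predictors are z-scored within participant before fitting so coefficient
magnitudes are mutually comparable.  A model is scored by the AUC of its
continuous preference score (the negated linear predictor) against the
chosen indicator, in-sample by default; an optional k-fold cross-validated
AUC over trials is available for out-of-sample evaluation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.miscmodels.ordinal_model import OrderedModel

from .feature_stats import GAZE_VARIABLES, PUPIL_VARIABLES, paired_comparison, rank_products, roc_auc

PREDICTOR_SETS: dict[str, tuple[str, ...]] = {
    "dwell_only": ("total_dwell_time",),
    "all_gaze": GAZE_VARIABLES,
    "gaze_plus_pupil": GAZE_VARIABLES + PUPIL_VARIABLES,
}

DEFAULT_BETA_CAP = 25.0
MIN_TRIALS = 10


@dataclass
class ParticipantModel:
    """A fitted per-participant cumulative-link preference model."""

    participant_id: str
    predictor_set: str
    predictors: tuple[str, ...]
    intercept: float
    betas: dict[str, float]
    auc: float
    n_trials: int
    llf: float = float("nan")
    converged: bool = True
    separation: bool = False
    # within-participant standardisation, stored for scoring new rows
    scale_mean: dict[str, float] = field(default_factory=dict)
    scale_sd: dict[str, float] = field(default_factory=dict)

    @property
    def beta_vector(self) -> np.ndarray:
        return np.array([self.betas[p] for p in self.predictors])


def _rank_transform(df: pd.DataFrame, predictors: Sequence[str]) -> pd.DataFrame:
    out = df.copy()
    for _, idx in df.groupby("trial_id").groups.items():
        block = df.loc[idx]
        for var in predictors:
            out.loc[idx, var] = rank_products(
                block[var].to_numpy(), block["product_id"].to_numpy()
            ).astype(float)
    return out


def _complete_rows(df: pd.DataFrame, predictors: Sequence[str]) -> pd.DataFrame:
    return df[np.isfinite(df[list(predictors)].to_numpy(dtype=float)).all(axis=1)]


def _zscore(X: np.ndarray, mean: np.ndarray, sd: np.ndarray) -> np.ndarray:
    sd_safe = np.where(sd > 0, sd, 1.0)
    Z = (X - mean) / sd_safe
    Z[:, sd == 0] = 0.0
    return Z


def _fit_ordered_logit(
    y: np.ndarray, Z: np.ndarray
) -> tuple[np.ndarray, float, bool, float]:
    """Fit the 2-category cumulative-link model.

    Returns (betas, cutpoint, converged, log-likelihood)."""
    model = OrderedModel(y, Z, distr="logit")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(method="bfgs", maxiter=200, disp=False)
    params = np.asarray(res.params, dtype=float)
    converged = bool(res.mle_retvals.get("converged", False))
    return params[: Z.shape[1]], float(params[Z.shape[1]]), converged, float(res.llf)


def fit_participant_model(
    features: pd.DataFrame,
    predictor_set: str = "all_gaze",
    use_ranks: bool = False,
    beta_cap: float = DEFAULT_BETA_CAP,
    min_trials: int = MIN_TRIALS,
) -> ParticipantModel:
    """Fit one participant's preference model on their feature table.

    ``features`` holds that participant's trial x product rows.  Rows with
    missing predictors (never-visited products, for pupil sets) are dropped;
    at least ``min_trials`` trials with complete predictors are required.
    """
    predictors = PREDICTOR_SETS[predictor_set]
    pid = str(features["participant_id"].iloc[0]) if "participant_id" in features else ""
    df = _rank_transform(features, predictors) if use_ranks else features
    df = _complete_rows(df, predictors)
    n_trials = df["trial_id"].nunique()
    if n_trials < min_trials:
        raise ValueError(
            f"participant {pid}: only {n_trials} trials with complete "
            f"predictors (need >= {min_trials})"
        )
    X = df[list(predictors)].to_numpy(dtype=float)
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    Z = _zscore(X, mean, sd)
    chosen = df["chosen"].to_numpy(dtype=bool)
    y = np.where(chosen, 0, 1)  # ordered: chosen < not chosen
    betas, cut, converged, llf = _fit_ordered_logit(y, Z)
    separation = bool(np.any(np.abs(betas) > beta_cap)) or not converged
    score = -(Z @ betas)  # higher score = more preferred
    auc = roc_auc(score[chosen], score[~chosen])
    betas = np.clip(betas, -beta_cap, beta_cap)
    return ParticipantModel(
        participant_id=pid,
        predictor_set=predictor_set,
        predictors=predictors,
        intercept=cut,
        betas=dict(zip(predictors, betas)),
        auc=auc,
        n_trials=n_trials,
        llf=llf,
        converged=converged,
        separation=separation,
        scale_mean=dict(zip(predictors, mean)),
        scale_sd=dict(zip(predictors, sd)),
    )


def model_auc(model: ParticipantModel, features: pd.DataFrame, use_ranks: bool = False) -> float:
    """AUC of the model's preference score on a feature table."""
    df = _rank_transform(features, model.predictors) if use_ranks else features
    df = _complete_rows(df, model.predictors)
    X = df[list(model.predictors)].to_numpy(dtype=float)
    mean = np.array([model.scale_mean[p] for p in model.predictors])
    sd = np.array([model.scale_sd[p] for p in model.predictors])
    score = -(_zscore(X, mean, sd) @ model.beta_vector)
    chosen = df["chosen"].to_numpy(dtype=bool)
    return roc_auc(score[chosen], score[~chosen])


def cross_validated_auc(
    features: pd.DataFrame,
    predictor_set: str,
    n_folds: int = 5,
    seed: int = 0,
    use_ranks: bool = False,
    beta_cap: float = DEFAULT_BETA_CAP,
) -> float:
    """Out-of-sample AUC via k-fold cross-validation over trials.

    Trials are shuffled deterministically (``seed``) and split into folds;
    each fold's products are scored by a model fitted on the remaining
    trials, and the pooled held-out scores yield one AUC.
    """
    predictors = PREDICTOR_SETS[predictor_set]
    df = _rank_transform(features, predictors) if use_ranks else features
    df = _complete_rows(df, predictors)
    trials = np.sort(df["trial_id"].unique())
    rng = np.random.default_rng(seed)
    rng.shuffle(trials)
    folds = np.array_split(trials, n_folds)
    scores = np.full(len(df), np.nan)
    chosen = df["chosen"].to_numpy(dtype=bool)
    trial_col = df["trial_id"].to_numpy()
    X = df[list(predictors)].to_numpy(dtype=float)
    for fold in folds:
        test = np.isin(trial_col, fold)
        if test.all() or not test.any():
            continue
        Xtr = X[~test]
        mean = Xtr.mean(axis=0)
        sd = Xtr.std(axis=0, ddof=0)
        Ztr = _zscore(Xtr, mean, sd)
        y = np.where(chosen[~test], 0, 1)
        betas, _, _, _ = _fit_ordered_logit(y, Ztr)
        betas = np.clip(betas, -beta_cap, beta_cap)
        scores[test] = -(_zscore(X[test], mean, sd) @ betas)
    keep = np.isfinite(scores)
    return roc_auc(scores[keep & chosen], scores[keep & ~chosen])


def fit_models(
    features: pd.DataFrame, predictor_set: str = "all_gaze", **kwargs
) -> list[ParticipantModel]:
    """Fit one model per participant in a pooled feature table."""
    return [
        fit_participant_model(grp, predictor_set, **kwargs)
        for _, grp in features.groupby("participant_id", sort=True)
    ]


def summarize_models(models: Sequence[ParticipantModel]) -> pd.DataFrame:
    """Across-participant mean +/- SD of AUC, intercept and each beta."""
    if not models:
        raise ValueError("no models to summarize")
    predictors = models[0].predictors
    rows = [
        {
            "quantity": "auc",
            "mean": float(np.mean([m.auc for m in models])),
            "sd": float(np.std([m.auc for m in models], ddof=1)),
        },
        {
            "quantity": "intercept",
            "mean": float(np.mean([m.intercept for m in models])),
            "sd": float(np.std([m.intercept for m in models], ddof=1)),
        },
    ]
    for p in predictors:
        vals = [m.betas[p] for m in models]
        rows.append(
            {
                "quantity": f"beta[{p}]",
                "mean": float(np.mean(vals)),
                "sd": float(np.std(vals, ddof=1)),
            }
        )
    return pd.DataFrame(rows).set_index("quantity")


@dataclass(frozen=True)
class ModelComparison:
    mean_diff: float
    sd_diff: float
    t: float
    df: int
    p: float


def compare_models(aucs_1: Sequence[float], aucs_2: Sequence[float]) -> ModelComparison:
    """Paired t-test on per-participant AUC differences (model 2 - model 1)."""
    a1 = np.asarray(aucs_1, dtype=float)
    a2 = np.asarray(aucs_2, dtype=float)
    if a1.shape != a2.shape:
        raise ValueError("AUC vectors must have equal length")
    res = paired_comparison(a2, a1)
    return ModelComparison(
        mean_diff=res.mean_diff, sd_diff=res.sd_diff, t=res.t, df=res.df, p=res.p
    )
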