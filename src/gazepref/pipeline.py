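"""End-to-end orchestration: recordings + areas + choices -> result tables.

The stages, per participant:

1. pupil preprocessing over the whole session (gap interpolation, then
   zero-phase detrending of the session-long drift);
2. per trial: baseline pupil from the phase-scrambled period, AOI labelling
   of the stimulus-phase samples, dwell segmentation;
3. the six per-product variables per trial;

and across participants: the preferred-vs-nonpreferred summary table,
rank-choice distributions, per-participant preference models for the three
nested predictor sets, and their pairwise comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import dwell_extraction, feature_stats, preference_model, pupil_preprocess
from .io_formats import ChoiceRecord, GazeRecording, ProductArea, choices_by_participant, validate_areas


@dataclass
class AnalysisConfig:
    """Tunable preprocessing/analysis settings with study defaults."""

    max_gap_s: float = 1.0  # longest blink/gap to interpolate
    cutoff_hz: float = 0.1  # detrend low-pass cutoff
    filter_order: int = 1
    bridge_gap_s: float = 1.0  # longest missing run absorbed into a dwell
    baseline_min_fraction: float = 0.5
    auc_pooling: str = "per_participant"
    use_ranks: bool = False  # rank-transformed predictors in the model
    cross_validate: bool = False  # out-of-sample model AUC (k-fold on trials)
    cv_folds: int = 5
    cv_seed: int = 0
    beta_cap: float = 25.0


def participant_features(
    recording: GazeRecording,
    areas_by_trial: Mapping[int, Sequence[ProductArea]],
    chosen_by_trial: Mapping[int, int],
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Six variables per trial x product for one participant."""
    cfg = config or AnalysisConfig()
    series = pupil_preprocess.PupilSeries.from_recording(recording)
    series = pupil_preprocess.interpolate_gaps(series, cfg.max_gap_s)
    decomp = pupil_preprocess.detrend_pupil(series, cfg.cutoff_hz, cfg.filter_order)

    s = recording.samples
    t = s["t"].to_numpy()
    x = s["x"].to_numpy()
    y = s["y"].to_numpy()
    valid = s["valid"].to_numpy()
    groups = s.groupby(["trial_id", "phase"], sort=False).indices

    frames = []
    for trial in recording.trial_ids:
        trial = int(trial)
        if trial not in chosen_by_trial:
            raise ValueError(
                f"participant {recording.participant_id}: no choice record "
                f"for trial {trial}"
            )
        base_idx = groups.get((trial, "baseline"), np.empty(0, dtype=int))
        if len(base_idx):
            window = (t[base_idx[0]], t[base_idx[-1]] + 1.0 / recording.fs)
            baseline = pupil_preprocess.baseline_pupil(
                series, window, cfg.baseline_min_fraction
            )
        else:
            baseline = float("nan")
        stim_idx = groups.get((trial, "stimulus"), np.empty(0, dtype=int))
        if not len(stim_idx):
            continue
        labels = dwell_extraction.assign_aoi(
            x[stim_idx], y[stim_idx], valid[stim_idx], areas_by_trial[trial]
        )
        dwells = dwell_extraction.extract_dwells(
            labels,
            recording.fs,
            bridge_gap=cfg.bridge_gap_s,
            trial_id=trial,
            t0=t[stim_idx[0]],
        )
        frames.append(
            feature_stats.compute_features(
                dwells,
                series.d[stim_idx],
                decomp.detrended[stim_idx],
                baseline,
                chosen_by_trial[trial],
                trial,
            )
        )
    out = pd.concat(frames, ignore_index=True)
    out.insert(0, "participant_id", recording.participant_id)
    return out


def extract_features(
    recordings: Sequence[GazeRecording],
    areas: Sequence[ProductArea],
    choices: Sequence[ChoiceRecord],
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Pooled feature table over all participants."""
    by_trial = validate_areas(areas)
    by_participant = choices_by_participant(choices)
    frames = [
        participant_features(rec, by_trial, by_participant[rec.participant_id], config)
        for rec in recordings
    ]
    return pd.concat(frames, ignore_index=True)


@dataclass
class AnalysisResult:
    """Everything the pipeline computes, ready for export or inspection."""

    features: pd.DataFrame
    table_one: pd.DataFrame
    rank_distribution: pd.DataFrame
    model_aucs: pd.DataFrame  # per participant x predictor set
    model_summaries: dict[str, pd.DataFrame]
    model_comparisons: pd.DataFrame


def model_aucs_by_set(
    features: pd.DataFrame,
    config: AnalysisConfig | None = None,
    predictor_sets: Sequence[str] = tuple(preference_model.PREDICTOR_SETS),
) -> pd.DataFrame:
    """Per-participant model AUC for each predictor set.

    In-sample by default; with ``config.cross_validate`` the AUC is the
    k-fold out-of-sample AUC over trials.
    """
    cfg = config or AnalysisConfig()
    rows = {}
    for name in predictor_sets:
        per_part = {}
        for pid, grp in features.groupby("participant_id", sort=True):
            if cfg.cross_validate:
                auc = preference_model.cross_validated_auc(
                    grp,
                    name,
                    n_folds=cfg.cv_folds,
                    seed=cfg.cv_seed,
                    use_ranks=cfg.use_ranks,
                    beta_cap=cfg.beta_cap,
                )
            else:
                auc = preference_model.fit_participant_model(
                    grp, name, use_ranks=cfg.use_ranks, beta_cap=cfg.beta_cap
                ).auc
            per_part[pid] = auc
        rows[name] = per_part
    return pd.DataFrame(rows)


def run_full_analysis(
    recordings: Sequence[GazeRecording],
    areas: Sequence[ProductArea],
    choices: Sequence[ChoiceRecord],
    config: AnalysisConfig | None = None,
) -> AnalysisResult:
    """The complete analysis: features, summary stats, models, comparisons."""
    cfg = config or AnalysisConfig()
    features = extract_features(recordings, areas, choices, cfg)
    t1 = feature_stats.table_one(features, pooling=cfg.auc_pooling)
    ranks = feature_stats.rank_choice_distribution(features)
    aucs = model_aucs_by_set(features, cfg)
    summaries = {
        name: preference_model.summarize_models(
            preference_model.fit_models(
                features, name, use_ranks=cfg.use_ranks, beta_cap=cfg.beta_cap
            )
        )
        for name in preference_model.PREDICTOR_SETS
    }
    comparisons = []
    for m1, m2 in (("dwell_only", "all_gaze"), ("all_gaze", "gaze_plus_pupil")):
        c = preference_model.compare_models(aucs[m1], aucs[m2])
        comparisons.append(
            {
                "model_1": m1,
                "model_2": m2,
                "mean_diff": c.mean_diff,
                "sd_diff": c.sd_diff,
                "t": c.t,
                "df": c.df,
                "p": c.p,
            }
        )
    return AnalysisResult(
        features=features,
        table_one=t1,
        rank_distribution=ranks,
        model_aucs=aucs,
        model_summaries=summaries,
        model_comparisons=pd.DataFrame(comparisons),
    )


def view_onset_traces(
    recording: GazeRecording,
    areas_by_trial: Mapping[int, Sequence[ProductArea]],
    chosen_by_trial: Mapping[int, int],
    window: float = 2.0,
    config: AnalysisConfig | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Event-locked mean pupil traces at preferred vs nonpreferred dwell onsets.

    Returns ``(lags, preferred_trace, nonpreferred_trace)`` averaged over all
    of the participant's dwell onsets, on the gap-interpolated pupil signal.
    """
    cfg = config or AnalysisConfig()
    series = pupil_preprocess.PupilSeries.from_recording(recording)
    series = pupil_preprocess.interpolate_gaps(series, cfg.max_gap_s)
    s = recording.samples
    t = s["t"].to_numpy()
    x = s["x"].to_numpy()
    y = s["y"].to_numpy()
    valid = s["valid"].to_numpy()
    groups = s.groupby(["trial_id", "phase"], sort=False).indices
    pref_onsets: list[float] = []
    nonpref_onsets: list[float] = []
    for trial in recording.trial_ids:
        trial = int(trial)
        stim_idx = groups.get((trial, "stimulus"), np.empty(0, dtype=int))
        if not len(stim_idx):
            continue
        labels = dwell_extraction.assign_aoi(
            x[stim_idx], y[stim_idx], valid[stim_idx], areas_by_trial[trial]
        )
        dwells = dwell_extraction.extract_dwells(
            labels, recording.fs, cfg.bridge_gap_s, trial, t0=t[stim_idx[0]]
        )
        chosen = chosen_by_trial[trial]
        for d in dwells:
            (pref_onsets if d.product_id == chosen else nonpref_onsets).append(d.t_start)
    lags, pref_trace, _ = feature_stats.event_locked_pupil(
        series.d, series.t, series.fs, pref_onsets, window
    )
    _, nonpref_trace, _ = feature_stats.event_locked_pupil(
        series.d, series.t, series.fs, nonpref_onsets, window
    )
    return lags, pref_trace, nonpref_trace
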