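"""Synthetic gaze/pupil experiments with the structure the analysis assumes.

The generator emulates a web-shop preference study: each of 61 participants
views 60 trials, each trial a 4 s phase-scrambled baseline screen followed
by a 15 s web-shop image showing five products.  One product per trial is
the participant's (latent) preference; the recorded choice always equals
it, and the pipeline's job is to recover it from gaze and pupil dynamics
alone.

Gaze is generated as a semi-Markov renewal process over visit targets (the
five product areas plus "outside"): each visit draws a target — never the
immediately preceding one, since consecutive same-target visits would merge
into a single dwell — with the preferred product's weight scaled by
``gaze_bias``, and a log-normal visit duration whose mean is larger for the
preferred product.  Within a visit, gaze coordinates are uniform over the
target rectangle.

The pupil trace is a participant-specific base diameter plus a slow
sinusoidal session drift, a small constant dilation (default 0.02 mm) while
gaze is inside the preferred product area, and white noise.  Blinks are
inserted as missing runs at a configurable rate, and further samples are
invalidated at random so the total expected data loss matches
``data_loss_rate`` (default 7.6%).

Everything is deterministic given ``seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .io_formats import (
    SCREEN_HEIGHT,
    SCREEN_WIDTH,
    ChoiceRecord,
    GazeRecording,
    N_PRODUCTS,
    ProductArea,
    write_aoi_table,
    write_choices,
    write_gaze_table,
)

OUTSIDE_TARGET = 0


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic experiment; defaults mirror the study
    conditions (61 analyzed participants x 60 trials at 30 Hz, ~7.6% data
    loss, a ~0.02 mm pupil dilation on the preferred product, and a dwell
    process biased toward it)."""

    n_participants: int = 61
    n_trials: int = 60
    fs: float = 30.0
    trial_duration: float = 15.0
    baseline_duration: float = 4.0
    gaze_bias: float = 1.5
    gaze_bias_trial_sd: float = 0.75  # per-trial preference-strength jitter
    dwell_duration_mean_pref: float = 0.45
    dwell_duration_mean_nonpref: float = 0.35
    dwell_duration_cv: float = 0.5
    outside_weight: float = 1.0
    outside_duration_mean: float = 0.30
    pupil_base: float = 3.3
    pupil_base_sd: float = 0.35
    pupil_drift_amplitude: float = 0.15
    pupil_drift_period: float = 900.0
    pupil_fluctuation_sd: float = 0.15  # spontaneous slow fluctuations, mm
    pupil_fluctuation_tau: float = 20.0  # their correlation time, s
    pupil_hippus_sd: float = 0.2  # in-band spontaneous oscillation (hippus), mm
    pupil_hippus_tau: float = 1.5  # its correlation time, s
    pupil_pref_effect: float = 0.02
    pupil_noise_sd: float = 0.05
    data_loss_rate: float = 0.076
    blink_rate: float = 12.0  # blinks per minute
    blink_duration: float = 0.25  # mean blink length, s
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "gaze_bias",
            "dwell_duration_mean_pref",
            "dwell_duration_mean_nonpref",
            "outside_weight",
            "outside_duration_mean",
            "pupil_noise_sd",
            "data_loss_rate",
            "blink_rate",
            "blink_duration",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 <= self.data_loss_rate < 1:
            raise ValueError("data_loss_rate must be in [0, 1)")
        for name in ("trial_duration", "baseline_duration"):
            n = self.fs * getattr(self, name)
            if abs(n - round(n)) > 1e-9:
                raise ValueError(f"fs x {name} must be an integral sample count")

    @property
    def n_baseline_samples(self) -> int:
        return int(round(self.fs * self.baseline_duration))

    @property
    def n_stimulus_samples(self) -> int:
        return int(round(self.fs * self.trial_duration))


@dataclass
class SimulatedExperiment:
    recordings: list[GazeRecording]
    areas: list[ProductArea]
    choices: list[ChoiceRecord]
    truth: pd.DataFrame | None = None


def default_areas(n_trials: int) -> list[ProductArea]:
    """Five equal product columns spanning the screen, same on every trial."""
    width = SCREEN_WIDTH // N_PRODUCTS
    y0, y1 = 240, 840
    return [
        ProductArea(
            trial_id=trial,
            product_id=p,
            x0=(p - 1) * width,
            y0=y0,
            x1=p * width,
            y1=y1,
        )
        for trial in range(1, n_trials + 1)
        for p in range(1, N_PRODUCTS + 1)
    ]


def _lognormal_params(mean: float, cv: float) -> tuple[float, float]:
    sigma2 = math.log1p(cv * cv)
    return math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)


def _simulate_trial_targets(
    cfg: GeneratorConfig, rng: np.random.Generator, preferred: int
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Per-sample visit target for one stimulus phase, plus the visit log.

    Preference strength varies across trials: the preferred product's visit
    weight and dwell-duration advantage are both raised to a per-trial
    exponent ~ N(1, ``gaze_bias_trial_sd``), so most trials show the
    configured gaze bias, some show almost none, and a small minority are
    reversed — gaze bias is a tendency, not a law.  Under a null
    configuration (bias 1, equal durations) the exponent has no effect.
    """
    n = cfg.n_stimulus_samples
    strength = rng.normal(1.0, cfg.gaze_bias_trial_sd)
    bias = cfg.gaze_bias**strength
    dur_ratio = (
        cfg.dwell_duration_mean_pref / cfg.dwell_duration_mean_nonpref
    ) ** strength
    pref_dur_mean = cfg.dwell_duration_mean_nonpref * dur_ratio
    ids = np.arange(N_PRODUCTS + 1)  # 0 = outside, 1..5 = products
    weights = np.ones(N_PRODUCTS + 1)
    weights[OUTSIDE_TARGET] = cfg.outside_weight
    weights[preferred] = bias
    mu_sig = {}
    for tgt in ids:
        if tgt == OUTSIDE_TARGET:
            mean = cfg.outside_duration_mean
        elif tgt == preferred:
            mean = pref_dur_mean
        else:
            mean = cfg.dwell_duration_mean_nonpref
        mu_sig[tgt] = _lognormal_params(mean, cfg.dwell_duration_cv)
    targets = np.empty(n, dtype=int)
    visits: list[tuple[int, int]] = []
    pos = 0
    prev = -1
    while pos < n:
        w = weights.copy()
        if prev >= 0:
            w[prev] = 0.0
        tgt = int(rng.choice(ids, p=w / w.sum()))
        mu, sigma = mu_sig[tgt]
        dur = float(rng.lognormal(mean=mu, sigma=sigma))
        ns = min(max(1, int(round(dur * cfg.fs))), n - pos)
        targets[pos : pos + ns] = tgt
        visits.append((tgt, ns))
        pos += ns
        prev = tgt
    return targets, visits


def _ou_process(
    sd: float, tau: float, fs: float, rng: np.random.Generator, n: int
) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck (AR(1)) noise: SD ``sd``, correlation
    time ``tau`` seconds.  Models the spontaneous wandering of pupil size —
    a slow arousal-linked component below the detrending cutoff and a
    faster in-band oscillation (hippus) above it."""
    if sd <= 0 or n == 0:
        return np.zeros(n)
    a = math.exp(-1.0 / (fs * tau))
    scale = math.sqrt(1.0 - a * a)
    eps = rng.normal(0.0, 1.0, n)
    eps[0] /= scale  # stationary start: out[0] ~ N(0, 1)
    out = lfilter([scale], [1.0, -a], eps)
    return sd * out


def _gaze_for_targets(
    targets: np.ndarray,
    areas: Sequence[ProductArea],
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample gaze coordinates uniformly within each sample's target region."""
    n = len(targets)
    x = np.empty(n)
    y = np.empty(n)
    rects = {a.product_id: a for a in areas}
    for tgt in np.unique(targets):
        mask = targets == tgt
        k = int(mask.sum())
        if tgt == OUTSIDE_TARGET:
            # outside strip: above or below the product row
            x[mask] = rng.uniform(0, SCREEN_WIDTH, k)
            top = rng.random(k) < 240.0 / (240.0 + (SCREEN_HEIGHT - 840.0))
            y[mask] = np.where(
                top, rng.uniform(0, 240, k), rng.uniform(840, SCREEN_HEIGHT, k)
            )
        else:
            a = rects[int(tgt)]
            x[mask] = rng.uniform(a.x0, a.x1, k)
            y[mask] = rng.uniform(a.y0, a.y1, k)
    return x, y


def simulate_recording(
    participant_id: str,
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    areas_by_trial: dict[int, list[ProductArea]],
) -> tuple[GazeRecording, list[ChoiceRecord], pd.DataFrame]:
    """One participant's full session: gaze TSV frame, choices, visit truth."""
    n_base = cfg.n_baseline_samples
    n_stim = cfg.n_stimulus_samples
    n_trial = n_base + n_stim
    n_total = cfg.n_trials * n_trial
    t = np.arange(n_total) / cfg.fs

    base = cfg.pupil_base + rng.normal(0, cfg.pupil_base_sd)
    base = max(base, 1.5)  # keep physiologically plausible
    drift_phase = rng.uniform(0, 2 * np.pi)
    preferred = rng.integers(1, N_PRODUCTS + 1, size=cfg.n_trials)

    x = np.empty(n_total)
    y = np.empty(n_total)
    on_pref = np.zeros(n_total, dtype=bool)
    trial_col = np.empty(n_total, dtype=int)
    phase_col = np.empty(n_total, dtype=object)
    truth_rows = []

    for k in range(cfg.n_trials):
        trial = k + 1
        lo = k * n_trial
        trial_col[lo : lo + n_trial] = trial
        phase_col[lo : lo + n_base] = "baseline"
        phase_col[lo + n_base : lo + n_trial] = "stimulus"
        # baseline: free viewing of the scramble, anywhere on screen
        x[lo : lo + n_base] = rng.uniform(0, SCREEN_WIDTH, n_base)
        y[lo : lo + n_base] = rng.uniform(0, SCREEN_HEIGHT, n_base)
        targets, visits = _simulate_trial_targets(cfg, rng, int(preferred[k]))
        sx, sy = _gaze_for_targets(targets, areas_by_trial[trial], rng)
        x[lo + n_base : lo + n_trial] = sx
        y[lo + n_base : lo + n_trial] = sy
        on_pref[lo + n_base : lo + n_trial] = targets == preferred[k]
        for tgt, ns in visits:
            if tgt != OUTSIDE_TARGET:
                truth_rows.append(
                    {
                        "participant_id": participant_id,
                        "trial_id": trial,
                        "product_id": tgt,
                        "n_samples": ns,
                        "preferred": tgt == preferred[k],
                    }
                )

    drift = cfg.pupil_drift_amplitude * np.sin(
        2 * np.pi * t / cfg.pupil_drift_period + drift_phase
    )
    pupil = (
        base
        + drift
        + _ou_process(cfg.pupil_fluctuation_sd, cfg.pupil_fluctuation_tau, cfg.fs, rng, n_total)
        + _ou_process(cfg.pupil_hippus_sd, cfg.pupil_hippus_tau, cfg.fs, rng, n_total)
        + cfg.pupil_pref_effect * on_pref
        + rng.normal(0, cfg.pupil_noise_sd, n_total)
    )

    # blinks: Poisson process over the session
    invalid = np.zeros(n_total, dtype=bool)
    minutes = n_total / cfg.fs / 60.0
    n_blinks = rng.poisson(cfg.blink_rate * minutes)
    if n_blinks:
        starts = np.sort(rng.uniform(0, t[-1], n_blinks))
        durs = rng.lognormal(*_lognormal_params(cfg.blink_duration, 0.3), n_blinks)
        for s, dur in zip(starts, durs):
            i0 = int(np.searchsorted(t, s))
            i1 = min(n_total, i0 + max(1, int(round(dur * cfg.fs))))
            invalid[i0:i1] = True
    # top up random sample loss so total expected loss hits data_loss_rate
    f_blink = invalid.mean()
    if f_blink < cfg.data_loss_rate:
        p_extra = (cfg.data_loss_rate - f_blink) / (1.0 - f_blink)
        invalid |= ~invalid & (rng.random(n_total) < p_extra)

    valid = ~invalid
    samples = pd.DataFrame(
        {
            "t": t,
            "x": np.where(valid, x, np.nan),
            "y": np.where(valid, y, np.nan),
            "pupil": np.where(valid, pupil, np.nan),
            "valid": valid,
            "trial_id": trial_col,
            "phase": phase_col,
        }
    )
    recording = GazeRecording(participant_id=participant_id, samples=samples, fs=cfg.fs)
    choices = [
        ChoiceRecord(participant_id=participant_id, trial_id=k + 1, chosen=int(preferred[k]))
        for k in range(cfg.n_trials)
    ]
    return recording, choices, pd.DataFrame(truth_rows)


def simulate_experiment(cfg: GeneratorConfig, with_truth: bool = False) -> SimulatedExperiment:
    """Generate a full experiment in memory, deterministic given cfg.seed."""
    areas = default_areas(cfg.n_trials)
    by_trial: dict[int, list[ProductArea]] = {}
    for a in areas:
        by_trial.setdefault(a.trial_id, []).append(a)
    children = np.random.SeedSequence(cfg.seed).spawn(cfg.n_participants)
    recordings = []
    choices: list[ChoiceRecord] = []
    truths = []
    for i, child in enumerate(children):
        pid = f"P{i + 1:03d}"
        rng = np.random.default_rng(child)
        rec, ch, truth = simulate_recording(pid, cfg, rng, by_trial)
        recordings.append(rec)
        choices.extend(ch)
        if with_truth:
            truths.append(truth)
    truth_df = pd.concat(truths, ignore_index=True) if truths else None
    return SimulatedExperiment(
        recordings=recordings, areas=areas, choices=choices, truth=truth_df
    )


def generate_experiment(cfg: GeneratorConfig, out_dir) -> dict[str, Path]:
    """Generate an experiment and write it to disk in the canonical dialects.

    Writes one ``<participant>.tsv`` gaze file per participant plus
    ``areas.csv`` and ``choices.csv``; returns the written paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sim = simulate_experiment(cfg)
    paths: dict[str, Path] = {}
    for rec in sim.recordings:
        p = out_dir / f"{rec.participant_id}.tsv"
        write_gaze_table(rec, p)
        paths[rec.participant_id] = p
    aoi_path = out_dir / "areas.csv"
    write_aoi_table(sim.areas, aoi_path)
    paths["areas"] = aoi_path
    choice_path = out_dir / "choices.csv"
    write_choices(sim.choices, choice_path)
    paths["choices"] = choice_path
    return paths


def effect_size_report(
    cfg: GeneratorConfig,
    recordings: Sequence[GazeRecording],
    features: pd.DataFrame,
) -> pd.DataFrame:
    """Generative parameter vs pipeline-recovered statistic, with rel. error.

    Covers the recoverable generator targets: data loss, the preferred-
    product pupil effect, the preferred/nonpreferred dwell-count ratio
    (generatively the visit-probability ratio ``gaze_bias``) and the two
    dwell-duration means.
    """
    pref = features[features["chosen"]]
    nonpref = features[~features["chosen"]]
    per_part = features.groupby(["participant_id", "chosen"])["mean_pupil"].mean().unstack()
    pupil_effect = float((per_part[True] - per_part[False]).mean())
    rows = [
        {
            "parameter": "data_loss_rate",
            "generative": cfg.data_loss_rate,
            "recovered": float(np.mean([r.data_loss for r in recordings])),
        },
        {
            "parameter": "pupil_pref_effect",
            "generative": cfg.pupil_pref_effect,
            "recovered": pupil_effect,
        },
        {
            "parameter": "dwell_count_ratio",
            "generative": cfg.gaze_bias,
            "recovered": float(pref["n_dwells"].mean() / nonpref["n_dwells"].mean()),
        },
        {
            "parameter": "dwell_duration_mean_pref",
            "generative": cfg.dwell_duration_mean_pref,
            "recovered": float(
                (pref["total_dwell_time"].sum() / pref["n_dwells"].sum())
            ),
        },
        {
            "parameter": "dwell_duration_mean_nonpref",
            "generative": cfg.dwell_duration_mean_nonpref,
            "recovered": float(
                (nonpref["total_dwell_time"].sum() / nonpref["n_dwells"].sum())
            ),
        },
    ]
    df = pd.DataFrame(rows).set_index("parameter")
    df["relative_error"] = (df["recovered"] - df["generative"]) / df["generative"]
    return df
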