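"""Pupil-signal cleaning: blink interpolation, slow-trend removal, baselines.

The pupil trace from a 30 Hz remote tracker carries three nuisance
components that must be handled before it can index preference:

* **Blinks and tracking dropouts** appear as runs of missing samples.  Short
  gaps (up to ``max_gap`` seconds, covering ordinary blinks) are filled with
  shape-preserving piecewise-cubic Hermite interpolation (pchip), which is
  monotone between knots and therefore cannot overshoot the flanking
  observed values.  Longer gaps stay missing and count as data loss.
* **Slow session drift** — pupil size typically declines gradually over the
  minutes of an experiment.  The drift is estimated with a first-order
  low-pass Butterworth filter (default cutoff 0.1 Hz) applied
  forward-backward (zero phase, so the trend is not shifted in time relative
  to the dwells) and subtracted, with the session mean restored so that
  detrended pupil size stays on the mm scale of the raw signal.
* **Tonic state at trial start** — the mean diameter during the 4 s
  phase-scrambled screen preceding each stimulus serves as the trial's
  baseline, against which stimulus-evoked dilation is measured.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.signal import butter, filtfilt

DEFAULT_CUTOFF_HZ = 0.1
DEFAULT_ORDER = 1
DEFAULT_MAX_GAP_S = 1.0


@dataclass
class PupilSeries:
    """A pupil-diameter time series; missing samples are NaN.

    ``interpolated`` flags samples whose value was filled rather than
    observed; observed samples are never altered by preprocessing.
    """

    t: np.ndarray
    d: np.ndarray
    fs: float
    interpolated: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.d = np.asarray(self.d, dtype=float)
        if self.interpolated is None:
            self.interpolated = np.zeros(len(self.d), dtype=bool)
        if len(self.t) != len(self.d):
            raise ValueError("t and d must have equal length")

    @classmethod
    def from_recording(cls, recording) -> "PupilSeries":
        s = recording.samples
        valid = s["valid"].to_numpy()
        return cls(
            t=s["t"].to_numpy(),
            d=np.where(valid, s["pupil"].to_numpy(), np.nan),
            fs=recording.fs,
        )

    @property
    def missing(self) -> np.ndarray:
        return ~np.isfinite(self.d)

    @property
    def observed(self) -> np.ndarray:
        return np.isfinite(self.d) & ~self.interpolated


@dataclass
class TrendDecomposition:
    """Low-frequency trend and mean-restored detrended pupil signal (mm)."""

    t: np.ndarray
    trend: np.ndarray
    detrended: np.ndarray
    fs: float
    session_mean: float


def _nan_runs(missing: np.ndarray) -> list[tuple[int, int]]:
    """(start, length) of each maximal run of True."""
    runs = []
    n = len(missing)
    i = 0
    while i < n:
        if missing[i]:
            j = i
            while j < n and missing[j]:
                j += 1
            runs.append((i, j - i))
            i = j
        else:
            i += 1
    return runs


def interpolate_gaps(series: PupilSeries, max_gap: float = DEFAULT_MAX_GAP_S) -> PupilSeries:
    """Fill missing runs of duration <= ``max_gap`` seconds with pchip.

    Gap duration is counted as (number of missing samples) / fs.  Gaps at
    the edges of the recording, and gaps longer than ``max_gap``, remain
    missing.  Observed samples pass through unchanged.
    """
    obs = np.isfinite(series.d)
    if obs.sum() < 2:
        raise ValueError("need at least two observed samples to interpolate")
    interp = PchipInterpolator(series.t[obs], series.d[obs])
    d = series.d.copy()
    flags = series.interpolated.copy()
    n = len(d)
    for start, length in _nan_runs(~obs):
        if start == 0 or start + length == n:
            continue  # edge gap: no flanking observations on both sides
        if length / series.fs > max_gap:
            continue  # too long: treated as data loss, left missing
        sl = slice(start, start + length)
        d[sl] = interp(series.t[sl])
        flags[sl] = True
    return PupilSeries(t=series.t, d=d, fs=series.fs, interpolated=flags)


def detrend_pupil(
    series: PupilSeries,
    cutoff_hz: float = DEFAULT_CUTOFF_HZ,
    order: int = DEFAULT_ORDER,
) -> TrendDecomposition:
    """Remove the slow drift with a zero-phase low-pass Butterworth filter.

    ``trend`` is the filtered signal; ``detrended`` is ``d - trend`` with the
    session mean restored, so its mean over usable samples equals the mean
    of the input exactly.  Remaining missing samples are bridged linearly
    for the filter's benefit only and stay missing in the output.
    """
    d = series.d
    n = len(d)
    b, a = butter(order, cutoff_hz, btype="low", fs=series.fs)
    padlen = 3 * max(len(a), len(b))
    if n <= padlen:
        raise ValueError(
            f"series of {n} samples is shorter than the filter warm-up "
            f"({padlen} samples); pad or concatenate before detrending"
        )
    finite = np.isfinite(d)
    if not finite.any():
        raise ValueError("cannot detrend an all-missing series")
    if finite.all():
        filled = d
    else:
        filled = np.interp(series.t, series.t[finite], d[finite])
    # symmetrised zero-phase filtering: averaging the forward and
    # time-reversed applications makes detrending exactly equivariant
    # under time reversal (filtfilt alone is only approximately so at a
    # cutoff this far below the sampling rate)
    trend = 0.5 * (filtfilt(b, a, filled) + filtfilt(b, a, filled[::-1])[::-1])
    session_mean = float(trend[finite].mean())
    detrended = np.where(finite, d - trend + session_mean, np.nan)
    trend = np.where(finite, trend, np.nan)
    return TrendDecomposition(
        t=series.t,
        trend=trend,
        detrended=detrended,
        fs=series.fs,
        session_mean=session_mean,
    )


def baseline_pupil(
    series: PupilSeries,
    baseline_window: tuple[float, float],
    min_fraction: float = 0.5,
) -> float:
    """Mean pupil diameter over ``[t0, t1)``; NaN if under-sampled.

    Observed and interpolated samples both count as usable.  If fewer than
    ``min_fraction`` of the window's samples are usable the baseline is
    flagged missing (NaN) and the trial should be excluded downstream.
    """
    t0, t1 = baseline_window
    mask = (series.t >= t0) & (series.t < t1)
    if not mask.any():
        return float("nan")
    vals = series.d[mask]
    usable = np.isfinite(vals)
    if usable.mean() < min_fraction:
        return float("nan")
    return float(vals[usable].mean())
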