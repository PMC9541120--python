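"""Readers, writers and validators for the pipeline's on-disk tables.

Three plain-text dialects are canonical:

* **Gaze file** — UTF-8 TSV with a header row and columns ``timestamp_s``,
  ``gaze_x_px``, ``gaze_y_px``, ``pupil_mm``, ``valid``, ``trial_id``,
  ``phase``.  One file per participant, samples in time order at a nominal
  30 Hz.  ``phase`` is one of ``baseline`` (phase-scrambled screen),
  ``stimulus`` (web-shop image) or ``question``.
* **AOI file** — CSV with columns ``trial_id, product_id, x0, y0, x1, y1``:
  per trial, five axis-aligned product rectangles in screen pixels.
* **Choice file** — CSV with columns ``participant_id, trial_id, chosen``.

Coordinate convention: pixel origin at the top-left, y grows downward, and
rectangles are half-open ``[x0, x1) x [y0, y1)`` so that abutting product
areas (the stimuli leave no space between them) never claim the same pixel.

A sample is *invalid* — and counts toward the reported data loss — when its
validity flag says so or when any of its gaze/pupil fields fails to parse as
a number; both collapse to the same missing-sample representation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

SCREEN_WIDTH = 1920
SCREEN_HEIGHT = 1080

GAZE_COLUMNS = (
    "timestamp_s",
    "gaze_x_px",
    "gaze_y_px",
    "pupil_mm",
    "valid",
    "trial_id",
    "phase",
)
PHASES = ("baseline", "stimulus", "question")
N_PRODUCTS = 5


class FormatError(ValueError):
    """A file does not conform to the expected on-disk dialect."""


class ValidationError(ValueError):
    """A file parses but violates a semantic invariant."""


@dataclass(frozen=True)
class ProductArea:
    """One product's half-open rectangle ``[x0,x1) x [y0,y1)`` on one image."""

    trial_id: int
    product_id: int
    x0: int
    y0: int
    x1: int
    y1: int

    def __post_init__(self) -> None:
        if not self.x0 < self.x1:
            raise ValidationError(
                f"trial {self.trial_id} product {self.product_id}: "
                f"x0 ({self.x0}) must be < x1 ({self.x1})"
            )
        if not self.y0 < self.y1:
            raise ValidationError(
                f"trial {self.trial_id} product {self.product_id}: "
                f"y0 ({self.y0}) must be < y1 ({self.y1})"
            )
        if self.x0 < 0 or self.y0 < 0 or self.x1 > SCREEN_WIDTH or self.y1 > SCREEN_HEIGHT:
            raise ValidationError(
                f"trial {self.trial_id} product {self.product_id}: rectangle "
                f"({self.x0},{self.y0})-({self.x1},{self.y1}) exceeds the "
                f"{SCREEN_WIDTH}x{SCREEN_HEIGHT} screen"
            )

    def contains(self, x, y):
        """Vectorised half-open containment test."""
        return (x >= self.x0) & (x < self.x1) & (y >= self.y0) & (y < self.y1)

    def overlaps(self, other: "ProductArea") -> bool:
        return (
            self.x0 < other.x1
            and other.x0 < self.x1
            and self.y0 < other.y1
            and other.y0 < self.y1
        )


@dataclass(frozen=True)
class ChoiceRecord:
    participant_id: str
    trial_id: int
    chosen: int

    def __post_init__(self) -> None:
        if not 1 <= self.chosen <= N_PRODUCTS:
            raise ValidationError(
                f"participant {self.participant_id} trial {self.trial_id}: "
                f"chosen product {self.chosen} outside 1-{N_PRODUCTS}"
            )


@dataclass
class GazeRecording:
    """A participant's time-ordered gaze/pupil sample stream.

    ``samples`` columns: ``t`` (s), ``x``/``y`` (px, NaN when invalid),
    ``pupil`` (mm, NaN when invalid), ``valid`` (bool), ``trial_id`` (int),
    ``phase`` (str).
    """

    participant_id: str
    samples: pd.DataFrame
    fs: float = 30.0

    def __post_init__(self) -> None:
        t = self.samples["t"].to_numpy()
        if len(t) and t[0] < 0:
            raise ValidationError("timestamps must be non-negative")
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValidationError("timestamps must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def data_loss(self) -> float:
        """Fraction of samples with invalid/missing gaze or pupil data."""
        if not len(self.samples):
            return 0.0
        return 1.0 - float(self.samples["valid"].mean())

    @property
    def trial_ids(self) -> np.ndarray:
        return np.unique(self.samples["trial_id"].to_numpy())


def _coerce_float(col: pd.Series) -> np.ndarray:
    """Parse strings to float64 with correct rounding; unparseable -> NaN.

    pandas' to_numeric is not a shortest-round-trip parser; numpy's is.
    """
    values = col.to_numpy(dtype=object)
    try:
        return np.asarray(np.where(values == "", "nan", values), dtype=float)
    except ValueError:
        def one(v):
            try:
                return float(v)
            except ValueError:
                return float("nan")
        return np.array([one(v) if v != "" else float("nan") for v in values])


def read_gaze_table(path, fs: float = 30.0, participant_id: str | None = None) -> GazeRecording:
    """Read one participant's gaze TSV.

    Rows with unparseable gaze/pupil numerics or a false validity flag
    become invalid samples (fields set to NaN); no row is silently dropped.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty gaze file") from None
    for col in GAZE_COLUMNS:
        if col not in raw.columns:
            raise FormatError(f"{path}: missing required column '{col}'")
    if not len(raw):
        raise FormatError(f"{path}: gaze file has a header but no samples")

    t = _coerce_float(raw["timestamp_s"])
    if not np.isfinite(t).all():
        raise FormatError(f"{path}: unparseable timestamp_s values")
    x = _coerce_float(raw["gaze_x_px"])
    y = _coerce_float(raw["gaze_y_px"])
    pupil = _coerce_float(raw["pupil_mm"])
    flag = pd.Series(np.nan_to_num(_coerce_float(raw["valid"])) != 0)
    trial = pd.to_numeric(raw["trial_id"], errors="coerce")
    if trial.isna().any():
        raise FormatError(f"{path}: unparseable trial_id values")
    phase = raw["phase"].str.strip()
    bad_phase = ~phase.isin(PHASES)
    if bad_phase.any():
        raise FormatError(
            f"{path}: unknown phase value '{phase[bad_phase].iloc[0]}' "
            f"(expected one of {', '.join(PHASES)})"
        )

    valid = (
        flag
        & np.isfinite(x)
        & np.isfinite(y)
        & np.isfinite(pupil)
        & (pupil > 0)
    )
    df = pd.DataFrame(
        {
            "t": t.astype(float),
            "x": np.where(valid, x, np.nan),
            "y": np.where(valid, y, np.nan),
            "pupil": np.where(valid, pupil, np.nan),
            "valid": valid.to_numpy(),
            "trial_id": trial.astype(int),
            "phase": phase,
        }
    )
    df = df.sort_values("t", kind="stable").reset_index(drop=True)
    pid = participant_id if participant_id is not None else path.stem
    return GazeRecording(participant_id=pid, samples=df, fs=fs)


def _float_repr(values) -> list[str]:
    # shortest round-trip decimal form; pandas' default can drop the 17th digit
    return ["" if not math.isfinite(v) else repr(float(v)) for v in values]


def write_gaze_table(recording: GazeRecording, path) -> None:
    """Write a gaze TSV; NaN fields are written empty.  Round-trips exactly."""
    s = recording.samples
    out = pd.DataFrame(
        {
            "timestamp_s": _float_repr(s["t"]),
            "gaze_x_px": _float_repr(s["x"]),
            "gaze_y_px": _float_repr(s["y"]),
            "pupil_mm": _float_repr(s["pupil"]),
            "valid": s["valid"].astype(int),
            "trial_id": s["trial_id"],
            "phase": s["phase"],
        }
    )
    out.to_csv(path, sep="\t", index=False)


def validate_areas(areas: Iterable[ProductArea]) -> dict[int, list[ProductArea]]:
    """Group areas per trial and enforce the five-disjoint-rectangles contract."""
    by_trial: dict[int, list[ProductArea]] = {}
    for a in areas:
        by_trial.setdefault(a.trial_id, []).append(a)
    for trial_id, group in by_trial.items():
        ids = sorted(a.product_id for a in group)
        if ids != list(range(1, N_PRODUCTS + 1)):
            raise ValidationError(
                f"trial {trial_id}: expected products 1-{N_PRODUCTS}, got {ids}"
            )
        group.sort(key=lambda a: a.product_id)
        for i, a in enumerate(group):
            for b in group[i + 1 :]:
                if a.overlaps(b):
                    raise ValidationError(
                        f"trial {trial_id}: product areas {a.product_id} and "
                        f"{b.product_id} overlap"
                    )
    return by_trial


def read_aoi_table(path) -> list[ProductArea]:
    """Read and validate the per-trial product-area CSV."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty AOI file") from None
    required = ("trial_id", "product_id", "x0", "y0", "x1", "y1")
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column '{col}'")
    areas = [
        ProductArea(
            trial_id=int(r.trial_id),
            product_id=int(r.product_id),
            x0=int(r.x0),
            y0=int(r.y0),
            x1=int(r.x1),
            y1=int(r.y1),
        )
        for r in df.itertuples()
    ]
    validate_areas(areas)
    return areas


def write_aoi_table(areas: Sequence[ProductArea], path) -> None:
    pd.DataFrame(
        [
            {
                "trial_id": a.trial_id,
                "product_id": a.product_id,
                "x0": a.x0,
                "y0": a.y0,
                "x1": a.x1,
                "y1": a.y1,
            }
            for a in areas
        ]
    ).to_csv(path, index=False)


def read_choices(path) -> list[ChoiceRecord]:
    """Read the choice CSV; exactly one record per participant x trial."""
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"participant_id": str})
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty choice file") from None
    for col in ("participant_id", "trial_id", "chosen"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column '{col}'")
    records = []
    seen: set[tuple[str, int]] = set()
    for r in df.itertuples():
        key = (str(r.participant_id), int(r.trial_id))
        if key in seen:
            raise ValidationError(
                f"duplicate choice record for participant {key[0]} trial {key[1]}"
            )
        seen.add(key)
        records.append(
            ChoiceRecord(participant_id=key[0], trial_id=key[1], chosen=int(r.chosen))
        )
    return records


def write_choices(records: Sequence[ChoiceRecord], path) -> None:
    pd.DataFrame(
        [
            {
                "participant_id": r.participant_id,
                "trial_id": r.trial_id,
                "chosen": r.chosen,
            }
            for r in records
        ]
    ).to_csv(path, index=False)


def choices_by_participant(records: Iterable[ChoiceRecord]) -> dict[str, dict[int, int]]:
    """Nest choice records as ``{participant_id: {trial_id: chosen}}``."""
    out: dict[str, dict[int, int]] = {}
    for r in records:
        out.setdefault(r.participant_id, {})[r.trial_id] = r.chosen
    return out
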