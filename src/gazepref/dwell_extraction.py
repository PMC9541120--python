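"""Map gaze samples to product areas and segment them into dwells.

A *dwell* is an uninterrupted period during which gaze stays inside a
single product area.  Unlike a fixation, a dwell spans any saccades and
blinks that occur while gaze remains in (or, for blinks, returns to) the
same area — dwell time accumulates from the moment gaze enters the area.

Per-sample labels are the product ids 1-5, ``OUTSIDE`` (0: a valid sample
not inside any area) or ``MISSING`` (-1: an invalid sample).  Segmentation
rules:

* maximal runs of one product label form dwells;
* a missing run no longer than ``bridge_gap`` seconds flanked on *both*
  sides by the same product is absorbed into one dwell (a blink while
  looking at a product counts as looking at it) and its samples count
  toward the dwell's duration;
* a single sample on another product or outside terminates the dwell, and
  outside runs are never bridged — gaze demonstrably left the area;
* missing runs at the edges of a trial, or flanked by different labels,
  are discarded.

There is no minimum dwell duration: one 33 ms sample is a valid dwell.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io_formats import ProductArea

OUTSIDE = 0
MISSING = -1

DEFAULT_BRIDGE_GAP_S = 1.0


@dataclass(frozen=True)
class Dwell:
    """One uninterrupted gaze period on a single product area.

    ``i_start`` is the index of the dwell's first sample within the label
    sequence it was extracted from, kept so that pupil samples can be
    aligned to the dwell without re-deriving time stamps.
    """

    trial_id: int
    product_id: int
    t_start: float
    t_end: float
    n_samples: int
    duration: float
    i_start: int = 0


def assign_aoi(
    x: np.ndarray,
    y: np.ndarray,
    valid: np.ndarray,
    areas: Sequence[ProductArea],
) -> np.ndarray:
    """Label each sample with its containing product area.

    Containment is half-open (``x0 <= x < x1``), so a sample on the shared
    edge of two abutting rectangles belongs to exactly one of them.  Samples
    outside every area (including off-screen) are ``OUTSIDE``; invalid or
    non-finite samples are ``MISSING``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    labels = np.full(len(x), OUTSIDE, dtype=int)
    with np.errstate(invalid="ignore"):
        for area in areas:
            labels[area.contains(x, y)] = area.product_id
    usable = np.asarray(valid, dtype=bool) & np.isfinite(x) & np.isfinite(y)
    labels[~usable] = MISSING
    return labels


def _run_lengths(labels: np.ndarray) -> list[list]:
    """Run-length encode ``labels`` as mutable [value, start, length] triples."""
    if not len(labels):
        return []
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(labels)]))
    return [[int(labels[s]), int(s), int(e - s)] for s, e in zip(starts, ends)]


def extract_dwells(
    labels: Sequence[int],
    fs: float,
    bridge_gap: float = DEFAULT_BRIDGE_GAP_S,
    trial_id: int = 0,
    t0: float = 0.0,
) -> list[Dwell]:
    """Segment a per-sample label sequence into dwells.

    ``t0`` is the time of the first sample; dwell times are reported as
    ``t0 + index / fs`` with ``t_end`` exclusive (the last sample's slot
    ends 1/fs after it starts), so ``t_end - t_start == duration``.
    """
    labels = np.asarray(labels, dtype=int)
    runs = _run_lengths(labels)
    # bridge short missing runs whose original flanks are the same product
    for k in range(1, len(runs) - 1):
        val, _, length = runs[k]
        if val != MISSING:
            continue
        prev_val, next_val = runs[k - 1][0], runs[k + 1][0]
        if prev_val == next_val and prev_val > 0 and length / fs <= bridge_gap:
            runs[k][0] = prev_val
    merged: list[list] = []
    for val, start, length in runs:
        if merged and merged[-1][0] == val:
            merged[-1][2] += length
        else:
            merged.append([val, start, length])
    return [
        Dwell(
            trial_id=trial_id,
            product_id=val,
            t_start=t0 + start / fs,
            t_end=t0 + (start + length) / fs,
            n_samples=length,
            duration=length / fs,
            i_start=start,
        )
        for val, start, length in merged
        if val > 0
    ]


def dwell_sample_indices(dwells: Sequence[Dwell]) -> np.ndarray:
    """Indices (into the label sequence) of every sample inside any dwell."""
    if not dwells:
        return np.empty(0, dtype=int)
    return np.concatenate(
        [np.arange(d.i_start, d.i_start + d.n_samples) for d in dwells]
    )
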