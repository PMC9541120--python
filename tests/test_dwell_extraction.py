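"""AOI assignment and dwell segmentation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gazepref.dwell_extraction import (
    MISSING,
    OUTSIDE,
    assign_aoi,
    extract_dwells,
)
from gazepref.io_formats import ProductArea

FS = 30.0
A, B = 1, 2


def areas_pair():
    """Two abutting rectangles sharing the x=400 edge."""
    return [
        ProductArea(1, 1, 0, 0, 400, 400),
        ProductArea(1, 2, 400, 0, 800, 400),
    ]


def dwell_tuples(dwells):
    return [(d.product_id, d.i_start, d.n_samples) for d in dwells]


class TestAssignAoi:
    def test_top_left_corner_belongs_to_area(self):
        labels = assign_aoi([0.0], [0.0], [True], areas_pair())
        assert labels[0] == 1

    def test_shared_edge_assigned_uniquely(self):
        # every pixel on the shared x=400 column belongs to area 2 only
        ys = np.arange(0, 400)
        xs = np.full_like(ys, 400)
        labels = assign_aoi(xs, ys, np.ones(len(ys), bool), areas_pair())
        assert (labels == 2).all()
        # and x=399 belongs to area 1 only
        labels = assign_aoi(np.full_like(ys, 399), ys, np.ones(len(ys), bool), areas_pair())
        assert (labels == 1).all()

    def test_bottom_right_corner_is_outside(self):
        labels = assign_aoi([400.0], [400.0], [True], [areas_pair()[0]])
        assert labels[0] == OUTSIDE

    def test_off_screen_is_outside(self):
        labels = assign_aoi([5000.0], [-10.0], [True], areas_pair())
        assert labels[0] == OUTSIDE

    def test_invalid_sample_is_missing(self):
        labels = assign_aoi([100.0, np.nan], [100.0, np.nan], [False, True], areas_pair())
        assert labels.tolist() == [MISSING, MISSING]


class TestExtractDwells:
    def test_hand_segmentation(self):
        labels = [A, A, A, B, B, A]
        dwells = extract_dwells(labels, FS)
        assert dwell_tuples(dwells) == [(A, 0, 3), (B, 3, 2), (A, 5, 1)]
        assert dwells[0].duration == pytest.approx(0.100)
        assert dwells[1].duration == pytest.approx(2 / 30)
        a_total = sum(d.duration for d in dwells if d.product_id == A)
        assert a_total == pytest.approx(4 / 30)

    def test_blink_bridged_into_one_dwell(self):
        labels = [A, A, MISSING, MISSING, A, A]
        dwells = extract_dwells(labels, FS, bridge_gap=2 / FS)
        assert dwell_tuples(dwells) == [(A, 0, 6)]
        assert dwells[0].duration == pytest.approx(6 / 30)

    def test_long_blink_splits_dwell(self):
        labels = [A, A] + [MISSING] * 40 + [A, A]
        dwells = extract_dwells(labels, FS, bridge_gap=1.0)
        assert dwell_tuples(dwells) == [(A, 0, 2), (A, 42, 2)]

    def test_missing_between_different_products_not_bridged(self):
        labels = [A, MISSING, B]
        dwells = extract_dwells(labels, FS, bridge_gap=1.0)
        assert dwell_tuples(dwells) == [(A, 0, 1), (B, 2, 1)]

    def test_outside_never_bridged(self):
        labels = [A, OUTSIDE, A]
        dwells = extract_dwells(labels, FS, bridge_gap=1.0)
        assert dwell_tuples(dwells) == [(A, 0, 1), (A, 2, 1)]

    def test_all_outside_yields_no_dwells(self):
        assert extract_dwells([OUTSIDE] * 10, FS) == []

    def test_edge_missing_runs_discarded(self):
        labels = [MISSING, A, A, MISSING]
        dwells = extract_dwells(labels, FS, bridge_gap=1.0)
        assert dwell_tuples(dwells) == [(A, 1, 2)]

    def test_timing_fields_consistent(self):
        dwells = extract_dwells([A, A, B], FS, trial_id=7, t0=10.0)
        d = dwells[0]
        assert d.trial_id == 7
        assert d.t_start == pytest.approx(10.0)
        assert d.t_end - d.t_start == pytest.approx(d.duration)


label_seqs = st.lists(
    st.sampled_from([A, B, OUTSIDE, MISSING]), min_size=0, max_size=30
)


class TestDwellProperties:
    @given(labels=label_seqs)
    @settings(max_examples=200, deadline=None)
    def test_reversal_mirrors_dwells(self, labels):
        fwd = extract_dwells(labels, FS, bridge_gap=2 / FS)
        rev = extract_dwells(labels[::-1], FS, bridge_gap=2 / FS)
        n = len(labels)
        mirrored = [
            (d.product_id, n - d.i_start - d.n_samples, d.n_samples)
            for d in reversed(rev)
        ]
        assert dwell_tuples(fwd) == mirrored

    @given(labels=label_seqs)
    @settings(max_examples=200, deadline=None)
    def test_conservation_of_samples(self, labels):
        dwells = extract_dwells(labels, FS, bridge_gap=2 / FS)
        n_in_dwells = sum(d.n_samples for d in dwells)
        assert n_in_dwells <= len(labels)
        if labels and all(l in (A, B) for l in labels):
            assert n_in_dwells == len(labels)

    @given(left=label_seqs, right=label_seqs)
    @settings(max_examples=200, deadline=None)
    def test_splitting_at_outside_sample_is_invariant(self, left, right):
        labels = left + [OUTSIDE] + right
        whole = dwell_tuples(extract_dwells(labels, FS, bridge_gap=2 / FS))
        first = dwell_tuples(extract_dwells(left + [OUTSIDE], FS, bridge_gap=2 / FS))
        # second half includes the outside cut sample at its local index 0,
        # so local index i maps to global index len(left) + i
        second = [
            (p, i + len(left), n)
            for p, i, n in dwell_tuples(
                extract_dwells([OUTSIDE] + right, FS, bridge_gap=2 / FS)
            )
        ]
        assert whole == first + second
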