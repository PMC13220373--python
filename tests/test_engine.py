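"""Streamline interception, spared fractions, weighting, binarization."""

import numpy as np
import pytest

from disconnectome import (
    StreamlineSet,
    ValidationError,
    binarize,
    densify_polyline,
    disconnection_fractions,
    streamline_intercepted,
    true_disconnection_fractions,
    weight_patient,
)

from conftest import make_mask


def brute_force_hit(points, mask, step=0.02):
    """Independent dense walk along each segment at a very fine step."""
    pts = np.asarray(points, float)
    for a, b in zip(pts[:-1], pts[1:]):
        n = max(2, int(np.linalg.norm(b - a) / step))
        for t in np.linspace(0, 1, n):
            v = tuple(np.floor(a + (b - a) * t).astype(int))
            if mask[v]:
                return True
    return bool(mask[tuple(np.floor(pts[-1]).astype(int))])


class TestInterception:
    def test_point_inside_lesion_hits(self):
        mask = np.zeros((8, 8, 8), bool); mask[3, 3, 3] = True
        line = np.array([[3.5, 3.5, 3.5], [6.0, 6.0, 6.0]])
        assert streamline_intercepted(line, mask)

    def test_empty_lesion_never_hits(self):
        mask = np.zeros((8, 8, 8), bool)
        line = np.array([[0.5, 0.5, 0.5], [7.5, 7.5, 7.5]])
        assert not streamline_intercepted(line, mask)

    def test_densification_catches_crossing_between_coarse_points(self):
        # two stored points straddle the lesion voxel; only densification
        # can see the crossing, which the fine-step walk confirms
        mask = np.zeros((12, 12, 12), bool); mask[5, 5, 5] = True
        line = np.array([[0.5, 5.5, 5.5], [10.5, 5.5, 5.5]])
        assert brute_force_hit(line, mask)
        assert streamline_intercepted(line, mask)

    def test_empty_polyline_rejected(self):
        with pytest.raises(ValidationError):
            streamline_intercepted(np.empty((0, 3)), np.zeros((4, 4, 4), bool))

    def test_densify_spacing_bound(self):
        line = np.array([[0.0, 0.0, 0.0], [9.3, 0.0, 0.0]])
        dense = densify_polyline(line, max_spacing=1.0)
        gaps = np.linalg.norm(np.diff(dense, axis=0), axis=1)
        assert gaps.max() <= 1.0 + 1e-12
        assert np.allclose(dense[0], line[0]) and np.allclose(dense[-1], line[-1])


def two_parcel_streams():
    streams = StreamlineSet(
        streamlines=[
            np.array([[0.5, 0.5, 0.5], [1.5, 0.5, 0.5], [2.5, 0.5, 0.5]]),
            np.array([[0.5, 1.5, 0.5], [1.5, 1.5, 0.5], [2.5, 1.5, 0.5]]),
            np.array([[0.5, 2.5, 0.5], [1.5, 2.5, 0.5], [2.5, 2.5, 0.5]]),
            np.array([[0.5, 3.5, 0.5], [1.5, 3.5, 0.5], [2.5, 3.5, 0.5]]),
        ],
        endpoints=np.array([[1, 2]] * 4),
    )
    healthy = np.zeros((2, 2), dtype=int)
    healthy[0, 1] = healthy[1, 0] = 4
    return streams, healthy


class TestFractions:
    def test_one_of_four_intercepted_gives_quarter(self):
        streams, healthy = two_parcel_streams()
        mask = np.zeros((4, 4, 4), bool); mask[1, 0, 0] = True  # hits first only
        frac = disconnection_fractions(streams, healthy, mask)
        assert frac.disconnection[0, 1] == pytest.approx(0.25)
        assert frac.spared[0, 1] == pytest.approx(0.75)
        assert np.array_equal(frac.spared, frac.spared.T)

    def test_full_grid_lesion_disconnects_everything(self):
        streams, healthy = two_parcel_streams()
        frac = disconnection_fractions(streams, healthy, np.ones((4, 4, 4), bool))
        assert frac.disconnection[0, 1] == 1.0

    def test_zero_healthy_pairs_carry_spared_one(self):
        streams, healthy = two_parcel_streams()
        frac = disconnection_fractions(streams, healthy, np.zeros((4, 4, 4), bool))
        assert frac.spared[0, 0] == 1.0  # diagonal / absent pairs spared by definition
        assert np.all(frac.spared + frac.disconnection == 1.0)

    def test_endpoint_pair_missing_from_healthy_rejected(self):
        streams, healthy = two_parcel_streams()
        healthy = np.zeros_like(healthy)
        with pytest.raises(ValidationError):
            disconnection_fractions(streams, healthy, np.zeros((4, 4, 4), bool))

    def test_matches_exhaustive_oracle_on_cohort(self, cohort):
        for mask, expected in zip(cohort.masks,
                                  cohort.truth.disconnection_fraction_true):
            frac = disconnection_fractions(cohort.streamlines, cohort.healthy, mask)
            assert np.array_equal(frac.disconnection, expected)

    def test_monotone_in_lesion_extent(self, cohort):
        # nested masks: bigger lesion, elementwise >= disconnection
        f1, f2 = (
            disconnection_fractions(cohort.streamlines, cohort.healthy, m).disconnection
            for m in cohort.masks[:2]
        )
        assert np.all(f2 <= f1 + 1e-12)


class TestWeighting:
    def test_elementwise_product(self):
        healthy = np.array([[0, 8], [8, 0]])
        spared = np.array([[1.0, 0.75], [0.75, 1.0]])
        w = weight_patient(healthy, spared)
        assert w[0, 1] == pytest.approx(6.0)

    def test_no_lesion_identity_and_full_lesion_zero(self, cohort):
        healthy = cohort.healthy
        assert np.array_equal(weight_patient(healthy, np.ones_like(healthy, float)),
                              healthy)
        w0 = weight_patient(healthy, np.zeros_like(healthy, float))
        assert not w0.any()

    def test_spared_outside_unit_interval_rejected(self):
        healthy = np.array([[0, 2], [2, 0]])
        with pytest.raises(ValidationError):
            weight_patient(healthy, np.full((2, 2), 1.5))

    def test_weights_bounded_by_healthy(self, cohort, nested_weighted):
        for w in nested_weighted:
            assert np.all(w <= cohort.healthy + 1e-12)
            assert np.all(np.diag(w) == 0)


class TestBinarize:
    def test_strictly_positive_rule(self):
        w = np.array([[0.0, 0.4], [0.4, 0.0]])
        assert binarize(w)[0, 1] == 1
        assert binarize(np.zeros((2, 2))).sum() == 0

    def test_fully_intercepted_pair_drops_out(self):
        streams, healthy = two_parcel_streams()
        frac = disconnection_fractions(streams, healthy, np.ones((4, 4, 4), bool))
        assert binarize(weight_patient(healthy, frac))[0, 1] == 0

    def test_empty_lesion_binary_equals_healthy_support(self, cohort):
        empty = make_mask(np.zeros(cohort.config.grid_shape))
        frac = disconnection_fractions(cohort.streamlines, cohort.healthy, empty)
        assert np.array_equal(binarize(weight_patient(cohort.healthy, frac)),
                              (cohort.healthy > 0).astype(int))


def test_oracle_hits_confirmed_by_fine_walk(moving_cohort):
    # every interception claimed by the ground-truth oracle must also be seen
    # by an independent, much finer per-segment walk (the walk visits a
    # superset of the stored points, so the implication is one-directional)
    mask = moving_cohort.masks[1].data
    truth = true_disconnection_fractions(
        moving_cohort.streamlines, moving_cohort.healthy, mask
    )
    checked = 0
    for pts, (i, j) in zip(moving_cohort.streamlines.streamlines,
                           moving_cohort.streamlines.endpoints):
        if moving_cohort.healthy[i - 1, j - 1] == 1 and truth[i - 1, j - 1] == 1.0:
            assert brute_force_hit(pts, mask)
            checked += 1
        if checked >= 20:
            break
    assert checked > 0
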