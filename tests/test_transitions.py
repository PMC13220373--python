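"""Longitudinal edge-change classification, counts, RSN attribution."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from disconnectome import (
    DegenerateInputError,
    classify_edges,
    count_changes,
    rsn_gain_loss,
    transition_pairs,
)
from disconnectome.engine import binarize
from disconnectome.transitions import CATEGORIES, lesion_covariate_table

from conftest import make_mask, weighted_series


def sym(entries, p):
    m = np.zeros((p, p))
    for i, j, v in entries:
        m[i - 1, j - 1] = m[j - 1, i - 1] = v
    return m


class TestClassification:
    @pytest.mark.parametrize(
        "wa, wb, expected",
        [
            (3.0, 0.0, "disconnection"),
            (0.0, 3.0, "re-emerging"),
            (10.0, 11.1, "over-connection"),   # +11% > 10%
            (10.0, 11.0, "persistent-other"),  # exactly +10% is not over
            (10.0, 9.0, "persistent-other"),
            (0.0, 0.0, "absent-both"),
        ],
    )
    def test_single_edge_categories(self, wa, wb, expected):
        table = classify_edges(sym([(1, 2, wa)], 2), sym([(1, 2, wb)], 2))
        assert table["category"].item() == expected

    def test_relative_change_formula_and_gaps(self):
        table = classify_edges(sym([(1, 2, 8.0), (1, 3, 2.0)], 3),
                               sym([(1, 2, 6.0), (1, 3, 0.0)], 3))
        row = table.set_index(["i", "j"])
        assert row.loc[(1, 2), "relative_change_pct"] == pytest.approx(-25.0)
        assert np.isnan(row.loc[(1, 3), "relative_change_pct"])  # not persistent

    def test_negative_weights_rejected(self):
        from disconnectome import ValidationError
        with pytest.raises(ValidationError):
            classify_edges(sym([(1, 2, -1.0)], 2), sym([(1, 2, 1.0)], 2))

    def test_nested_shrinkage_yields_no_disconnections(self, nested_weighted):
        for a, b in transition_pairs(3):
            table = classify_edges(nested_weighted[a], nested_weighted[b])
            assert (table["category"] != "disconnection").all()
            rel = table["relative_change_pct"].dropna()
            assert (rel >= 0).all()

    def test_matches_ground_truth_categories(self, moving_cohort, moving_weighted):
        for (a, b), truth_cats in moving_cohort.truth.edge_category_true.items():
            table = classify_edges(moving_weighted[a], moving_weighted[b])
            got = {(int(r.i), int(r.j)): r.category for r in table.itertuples()}
            for pair, expected in truth_cats.items():
                assert got[pair] == expected

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, derandomize=True, deadline=None)
    def test_partition_property(self, seed):
        rng = np.random.default_rng(seed)
        p = 8
        w = rng.integers(0, 4, size=(2, p, p)).astype(float)
        wa = np.triu(w[0], 1); wa = wa + wa.T
        wb = np.triu(w[1], 1); wb = wb + wb.T
        table = classify_edges(wa, wb)
        assert len(table) == p * (p - 1) // 2
        assert set(table["category"]) <= set(CATEGORIES)
        # the three analysis categories are mutually exclusive per edge by
        # construction of the single category column; check counts partition
        assert table["category"].value_counts().sum() == p * (p - 1) // 2


class TestCounts:
    def test_normalisation_by_baseline_edges(self):
        wa = sym([(i, j, 1.0) for i in range(1, 11) for j in range(i + 1, 11)], 10)
        wb = wa.copy()
        # remove 5 of the 45 edges
        for i, j in [(1, 2), (1, 3), (1, 4), (1, 5), (1, 6)]:
            wb[i - 1, j - 1] = wb[j - 1, i - 1] = 0.0
        counts = count_changes(classify_edges(wa, wb), binarize(wa))
        assert counts.n_disconnections == 5
        assert counts.n_existing_baseline == 45
        assert counts.pct_disconnections == pytest.approx(100 * 5 / 45)

    def test_planted_category_counts(self):
        p = 8
        entries_a, entries_b = [], []
        # 2 disconnections
        entries_a += [(1, 2, 1.0), (1, 3, 1.0)]
        # 3 re-emerging
        entries_b += [(2, 3, 1.0), (2, 4, 1.0), (2, 5, 1.0)]
        # 4 over-connections (+50%)
        for i, j in [(3, 4), (3, 5), (4, 5), (6, 7)]:
            entries_a.append((i, j, 2.0)); entries_b.append((i, j, 3.0))
        # 1 stable persistent edge
        entries_a.append((7, 8, 5.0)); entries_b.append((7, 8, 5.0))
        counts = count_changes(
            classify_edges(sym(entries_a, p), sym(entries_b, p)),
            binarize(sym(entries_a, p)),
        )
        assert (counts.n_disconnections, counts.n_reemerging,
                counts.n_overconnections) == (2, 3, 4)

    def test_identical_matrices_no_changes(self, nested_weighted):
        w = nested_weighted[0]
        counts = count_changes(classify_edges(w, w), binarize(w))
        assert counts.n_disconnections == counts.n_reemerging == 0
        assert counts.n_overconnections == 0

    def test_zero_baseline_edges_rejected(self):
        w0 = np.zeros((3, 3))
        with pytest.raises(DegenerateInputError):
            count_changes(classify_edges(w0, w0), binarize(w0))

    def test_counts_invariant_under_parcel_relabelling(self, moving_weighted):
        wa, wb = moving_weighted[0], moving_weighted[1]
        rng = np.random.default_rng(0)
        perm = rng.permutation(wa.shape[0])
        wa_p = wa[np.ix_(perm, perm)]
        wb_p = wb[np.ix_(perm, perm)]
        c = count_changes(classify_edges(wa, wb), binarize(wa))
        c_p = count_changes(classify_edges(wa_p, wb_p), binarize(wa_p))
        assert c == c_p

    def test_threshold_limits(self, moving_weighted):
        wa, wb = moving_weighted[0], moving_weighted[1]
        huge = count_changes(classify_edges(wa, wb, over_threshold_pct=1e9),
                             binarize(wa))
        assert huge.n_overconnections == 0
        tiny = classify_edges(wa, wb, over_threshold_pct=1e-12)
        rel = tiny["relative_change_pct"]
        expect = int(((rel > 1e-12)).sum())
        assert (tiny["category"] == "over-connection").sum() == expect


class TestRSNGainLoss:
    def test_dual_attribution_and_intra_once(self):
        network_of = {1: "X", 2: "Y", 3: "X", 4: "X"}
        wa = sym([(3, 4, 1.0)], 4)          # intra-X edge, will disconnect
        wb = sym([(1, 2, 1.0)], 4)          # X-Y edge re-emerges
        table = classify_edges(wa, wb)
        gl = rsn_gain_loss(table, network_of).set_index("network")
        assert gl.loc["X", "gained"] == 1 and gl.loc["Y", "gained"] == 1
        assert gl.loc["X", "lost"] == 1 and gl.loc["Y", "lost"] == 0
        assert gl.loc["X", "difference"] == 0 and gl.loc["Y", "difference"] == 1

    def test_no_changes_all_zero(self, nested_weighted, cohort):
        w = nested_weighted[0]
        gl = rsn_gain_loss(classify_edges(w, w), cohort.atlas.networks)
        assert (gl[["gained", "lost", "difference"]].to_numpy() == 0).all()

    def test_three_intra_network_losses(self):
        network_of = {1: "X", 2: "X", 3: "X", 4: "Y"}
        wa = sym([(1, 2, 1.0), (1, 3, 1.0), (2, 3, 1.0)], 4)
        gl = rsn_gain_loss(classify_edges(wa, np.zeros((4, 4))), network_of)
        gl = gl.set_index("network")
        assert gl.loc["X", "difference"] == -3
        assert gl.loc["Y", "difference"] == 0


class TestCompositionAndCovariates:
    def test_disconnect_then_reemerge_is_persistent_overall(self, moving_weighted):
        w1, w2, w3 = moving_weighted
        c12 = classify_edges(w1, w2).set_index(["i", "j"])["category"]
        c23 = classify_edges(w2, w3).set_index(["i", "j"])["category"]
        c13 = classify_edges(w1, w3).set_index(["i", "j"])["category"]
        flip = (c12 == "disconnection") & (c23 == "re-emerging")
        assert flip.any()  # the moving lesion must exercise this path
        assert c13[flip].isin(["persistent-other", "over-connection"]).all()

    def test_identical_masks_give_null_covariates(self, cohort, nested_weighted):
        mask = cohort.masks[0]
        w = nested_weighted[0]
        counts = {(0, 1): count_changes(classify_edges(w, w), binarize(w))}
        masks = [mask, make_mask(mask.data.copy(), timepoint="S2")]
        table = lesion_covariate_table(masks, counts)
        row = table.iloc[0]
        assert row["dsc"] == 1.0
        assert row["volume_pct_change"] == 0.0
        assert row["n_disconnections"] == 0 and row["n_reemerging"] == 0

    def test_shrinkage_covariates(self, cohort, nested_weighted):
        counts = {}
        for a, b in transition_pairs(3):
            table = classify_edges(nested_weighted[a], nested_weighted[b])
            counts[(a, b)] = count_changes(table, binarize(nested_weighted[a]))
        cov = lesion_covariate_table(cohort.masks, counts)
        assert (cov["volume_pct_change"] > 0).all()
        assert (cov["n_disconnections"] == 0).all()
        assert (cov["n_reemerging"] >= 0).all()

    def test_jittered_masks_have_partial_overlap(self, moving_cohort, moving_weighted):
        counts = {}
        for a, b in transition_pairs(3):
            table = classify_edges(moving_weighted[a], moving_weighted[b])
            counts[(a, b)] = count_changes(table, binarize(moving_weighted[a]))
        cov = lesion_covariate_table(moving_cohort.masks, counts).set_index("transition")
        assert (cov["dsc"] < 1.0).all()
        assert cov["n_disconnections"].sum() > 0
        assert cov["n_reemerging"].sum() > 0
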