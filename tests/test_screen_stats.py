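"""qPCR fold changes, perturbation ranking, clustering, summaries, correlation."""

import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from organoscreen.screen_stats import (
    DEFAULT_MARKER_PANEL,
    cluster_tree,
    correlate,
    delta_ct,
    fold_change,
    median_timecourse,
    perturbation,
    summarize_distribution,
)


def ct_long(rows):
    return pd.DataFrame(rows, columns=["replicate", "treatment", "well", "gene", "ct"])


def fc_frame(data, genes, index):
    idx = pd.MultiIndex.from_tuples(index, names=["replicate", "treatment"])
    return pd.DataFrame(data, index=idx, columns=genes)


class TestDeltaCt:
    def test_direct_substitution(self):
        ct = ct_long(
            [("R1", "X", 1, "Hprt", 20.0), ("R1", "X", 1, "Lgr5", 25.0)]
        )
        dct = delta_ct(ct)
        assert dct.loc[("R1", "X", 1), "Lgr5"] == -5.0

    def test_housekeeping_self_reference_zero(self):
        ct = ct_long([("R1", "X", 1, "Hprt", 21.5)])
        assert delta_ct(ct).loc[("R1", "X", 1), "Hprt"] == 0.0

    def test_missing_ct_stays_missing(self):
        ct = ct_long(
            [("R1", "X", 1, "Hprt", 20.0), ("R1", "X", 1, "Lgr5", np.nan)]
        )
        assert np.isnan(delta_ct(ct).loc[("R1", "X", 1), "Lgr5"])

    def test_technical_replicates_averaged(self):
        ct = pd.DataFrame(
            {
                "replicate": ["R1"] * 4,
                "treatment": ["X"] * 4,
                "well": [1] * 4,
                "technical_rep": [1, 2, 1, 2],
                "gene": ["Hprt", "Hprt", "Lgr5", "Lgr5"],
                "ct": [20.0, 21.0, 24.0, 25.0],
            }
        )
        assert delta_ct(ct).loc[("R1", "X", 1), "Lgr5"] == pytest.approx(20.5 - 24.5)

    def test_missing_housekeeping_warns_and_blanks_sample(self, caplog):
        import logging

        ct = ct_long(
            [("R1", "X", 1, "Hprt", np.nan), ("R1", "X", 1, "Lgr5", 24.0)]
        )
        with caplog.at_level(logging.WARNING, logger="organoscreen.screen_stats"):
            dct = delta_ct(ct)
        assert np.isnan(dct.loc[("R1", "X", 1), "Lgr5"])
        assert any("housekeeping" in r.message for r in caplog.records)

    def test_absent_housekeeping_gene_rejected(self):
        ct = ct_long([("R1", "X", 1, "Lgr5", 24.0)])
        with pytest.raises(ValueError, match="Hprt"):
            delta_ct(ct)

    def test_ct_range_validated(self):
        ct = ct_long([("R1", "X", 1, "Hprt", 50.0)])
        with pytest.raises(ValueError, match=r"\(0, 45\]"):
            delta_ct(ct)


class TestFoldChange:
    def base_dct(self):
        ct = ct_long(
            [
                ("R1", "DMSO", w, g, v)
                for w in (1, 2)
                for g, v in (("Hprt", 20.0), ("Lgr5", 24.0))
            ]
            + [("R1", "X", 1, "Hprt", 20.0), ("R1", "X", 1, "Lgr5", 23.0)]
        )
        return delta_ct(ct)

    def test_powers_of_two(self):
        dct = self.base_dct()
        fc = fold_change(dct, calibrator="DMSO")
        # X has dCT -3 vs calibrator mean -4: ddCT = 1 -> xfold 2
        assert fc.loc[("R1", "X"), "Lgr5"] == pytest.approx(2.0)
        assert fc.loc[("R1", "DMSO"), "Lgr5"] == pytest.approx(1.0)
        assert fc.loc[("R1", "X"), "Hprt"] == pytest.approx(1.0)

    def test_negative_ddct(self):
        ct = ct_long(
            [
                ("R1", "DMSO", 1, "Hprt", 20.0),
                ("R1", "DMSO", 1, "Lgr5", 24.0),
                ("R1", "X", 1, "Hprt", 20.0),
                ("R1", "X", 1, "Lgr5", 26.0),
            ]
        )
        fc = fold_change(delta_ct(ct), calibrator="DMSO")
        assert fc.loc[("R1", "X"), "Lgr5"] == pytest.approx(0.25)

    def test_calibrator_self_normalization(self):
        rng = np.random.default_rng(1)
        rows = []
        for rep in ("R1", "R2"):
            for w in range(1, 5):
                rows.append((rep, "DMSO", w, "Hprt", rng.uniform(19, 21)))
                rows.append((rep, "DMSO", w, "Lgr5", rng.uniform(23, 25)))
        fc = fold_change(delta_ct(ct_long(rows)), calibrator="DMSO")
        log2_means = np.log2(fc["Lgr5"]).groupby(level="replicate").mean()
        np.testing.assert_allclose(log2_means, 0.0, atol=1e-12)

    def test_missing_calibrator_rejected(self):
        dct = self.base_dct()
        with pytest.raises(ValueError, match="calibrator"):
            fold_change(dct, calibrator="nope")

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.floats(-5, 5))
    def test_global_ct_shift_invariance(self, shift):
        """Shifting all of one sample's CTs (genes + housekeeping) by a
        constant leaves its fold changes unchanged."""
        base = ct_long(
            [
                ("R1", "DMSO", 1, "Hprt", 20.0),
                ("R1", "DMSO", 1, "Lgr5", 24.0),
                ("R1", "X", 1, "Hprt", 21.0),
                ("R1", "X", 1, "Lgr5", 23.5),
            ]
        )
        shifted = base.copy()
        shifted.loc[shifted.treatment == "X", "ct"] += shift
        fc_a = fold_change(delta_ct(base), calibrator="DMSO")
        fc_b = fold_change(delta_ct(shifted), calibrator="DMSO")
        np.testing.assert_allclose(
            fc_a.loc[("R1", "X")].to_numpy(), fc_b.loc[("R1", "X")].to_numpy(), atol=1e-9
        )


class TestPerturbation:
    def test_null_perturbation_not_flagged(self):
        fc = fc_frame([[1.0] * 12], list(DEFAULT_MARKER_PANEL), [("R1", "X")])
        out = perturbation(fc)
        assert out.loc[0, "distance"] == 0.0
        assert np.isnan(out.loc[0, "log2_distance"])  # never -inf
        assert not out.loc[0, "flagged_followup"]

    def test_single_coordinate_norm(self):
        values = [[4.0] + [1.0] * 11]
        fc = fc_frame(values, list(DEFAULT_MARKER_PANEL), [("R1", "X")])
        out = perturbation(fc)
        assert out.loc[0, "distance"] == pytest.approx(2.0)
        assert out.loc[0, "log2_distance"] == pytest.approx(1.0)
        assert not out.loc[0, "flagged_followup"]

    def test_twelve_genes_at_twofold_flagged(self):
        fc = fc_frame([[2.0] * 12], list(DEFAULT_MARKER_PANEL), [("R1", "X")])
        out = perturbation(fc)
        assert out.loc[0, "distance"] == pytest.approx(np.sqrt(12.0))
        assert out.loc[0, "log2_distance"] == pytest.approx(1.7925, abs=1e-4)
        assert out.loc[0, "flagged_followup"]

    def test_gene_exclusion_shrinks_panel(self):
        fc = fc_frame([[2.0] * 12], list(DEFAULT_MARKER_PANEL), [("R1", "X")])
        out = perturbation(fc, exclude_genes=["Defa22"])
        assert out.loc[0, "distance"] == pytest.approx(np.sqrt(11.0))
        assert "Defa22" not in out.attrs["genes_used"]

    def test_treatment_exclusion_reported_not_ranked(self):
        fc = fc_frame(
            [[2.0] * 12, [2.0] * 12],
            list(DEFAULT_MARKER_PANEL),
            [("R1", "X"), ("R1", "VPA")],
        )
        out = perturbation(fc, exclude_treatments=["VPA"])
        row = out[out.treatment == "VPA"].iloc[0]
        assert row["excluded_from_ranking"]
        assert not row["flagged_followup"]
        assert row["distance"] == pytest.approx(np.sqrt(12.0))

    def test_gene_with_missing_median_dropped(self, caplog):
        import logging

        data = [[2.0] * 12]
        fc = fc_frame(data, list(DEFAULT_MARKER_PANEL), [("R1", "X")])
        fc.loc[("R1", "X"), "Muc2"] = np.nan
        with caplog.at_level(logging.WARNING, logger="organoscreen.screen_stats"):
            out = perturbation(fc)
        assert "Muc2" not in out.attrs["genes_used"]
        assert out.loc[0, "distance"] == pytest.approx(np.sqrt(11.0))

    def test_median_across_replicates(self):
        fc = fc_frame(
            [[1.0] * 12, [2.0] * 12, [4.0] * 12],
            list(DEFAULT_MARKER_PANEL),
            [("R1", "X"), ("R2", "X"), ("R3", "X")],
        )
        out = perturbation(fc)
        assert out.loc[0, "distance"] == pytest.approx(np.sqrt(12.0))  # median xfold 2


class TestClusterTree:
    def test_identical_rows_merge_at_zero(self):
        m = pd.DataFrame([[1.0, 2.0], [1.0, 2.0], [5.0, 5.0]], index=["a", "b", "c"])
        tree = cluster_tree(m)
        assert tree.linkage[0, 2] == 0.0

    def test_three_points_on_a_line(self):
        m = pd.DataFrame([[0.0], [1.0], [10.0]], index=["a", "b", "c"])
        tree = cluster_tree(m)
        first = tree.linkage[0]
        assert {int(first[0]), int(first[1])} == {0, 1}
        assert first[2] == pytest.approx(1.0)
        # complete linkage: root merge at max distance 10
        assert tree.linkage[-1, 2] == pytest.approx(10.0)

    def test_permutation_invariant_topology(self):
        rng = np.random.default_rng(4)
        m = pd.DataFrame(rng.normal(size=(6, 3)), index=list("abcdef"))
        perm = m.sample(frac=1, random_state=1)
        t1, t2 = cluster_tree(m), cluster_tree(perm)
        from scipy.cluster.hierarchy import cophenet
        from scipy.spatial.distance import squareform

        c1 = pd.DataFrame(squareform(cophenet(t1.linkage)), index=m.index, columns=m.index)
        c2 = pd.DataFrame(
            squareform(cophenet(t2.linkage)), index=perm.index, columns=perm.index
        )
        np.testing.assert_allclose(
            c1.loc[list("abcdef"), list("abcdef")],
            c2.loc[list("abcdef"), list("abcdef")],
            atol=1e-9,
        )

    def test_missing_values_rejected(self):
        m = pd.DataFrame([[1.0, np.nan], [0.0, 1.0]])
        with pytest.raises(ValueError, match="missing"):
            cluster_tree(m)

    def test_single_row_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            cluster_tree(pd.DataFrame([[1.0]]))

    def test_newick_parseable(self):
        import skbio

        m = pd.DataFrame(
            np.arange(12, dtype=float).reshape(4, 3), index=["w", "x", "y", "z"]
        )
        text = cluster_tree(m).to_newick()
        tree = skbio.TreeNode.read(io.StringIO(text))
        assert {t.name for t in tree.tips()} == {"w", "x", "y", "z"}


class TestCorrelate:
    def test_perfect_positive_linearity(self):
        x = np.arange(10, dtype=float)
        r, p = correlate(x, 2 * x + 3)
        assert r == pytest.approx(1.0)
        assert p < 1e-8

    def test_perfect_negative(self):
        x = np.arange(5, dtype=float)
        r, _ = correlate(x, -x)
        assert r == pytest.approx(-1.0)

    def test_matches_closed_form(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        r, _ = correlate(x, y)
        oracle = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert r == pytest.approx(oracle, abs=1e-12)

    def test_zero_variance_undefined(self):
        r, p = correlate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert np.isnan(r) and np.isnan(p)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="n >= 3"):
            correlate([1.0, 2.0], [1.0, 2.0])


class TestSummarize:
    def test_one_to_hundred_quartiles(self):
        s = summarize_distribution(np.arange(1, 101, dtype=float))
        assert s.q25 == pytest.approx(25.75)
        assert s.q50 == pytest.approx(50.5)
        assert s.q75 == pytest.approx(75.25)
        assert s.outlier_count == 0

    def test_constant_sample(self):
        s = summarize_distribution([7.0] * 5)
        assert s.q25 == s.q50 == s.q75 == 7.0
        assert s.whisker_low == s.whisker_high == 7.0
        assert s.outlier_count == 0

    def test_extreme_value_is_outlier(self):
        s = summarize_distribution([1.0, 2.0, 3.0, 1000.0])
        # q25=1.75, q75=252.25 -> IQR 250.5, hi fence 628
        assert s.outlier_count == 1
        assert s.whisker_high == 3.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            summarize_distribution([])


class TestMedianTimecourse:
    def objects(self):
        rows = []
        for rep, wells in (("R1", {"w1": [1.0, 2.0, 3.0]}),):
            for well, areas in wells.items():
                for a in areas:
                    rows.append(
                        {
                            "treatment": "X",
                            "replicate": rep,
                            "well_id": well,
                            "timepoint_h": 96.0,
                            "area_um2": a,
                        }
                    )
        return pd.DataFrame(rows)

    def test_single_well_median(self):
        out = median_timecourse(self.objects())
        well_row = out[out.level == "well"].iloc[0]
        assert well_row["median_value"] == 2.0

    def test_even_replicate_median(self):
        rows = []
        for i, med in enumerate([10.0, 20.0, 30.0, 40.0]):
            rows.append(
                {
                    "treatment": "X",
                    "replicate": f"R{i}",
                    "well_id": "w1",
                    "timepoint_h": 96.0,
                    "area_um2": med,
                }
            )
        out = median_timecourse(pd.DataFrame(rows))
        treat = out[out.level == "treatment"].iloc[0]
        assert treat["median_value"] == 25.0

    def test_object_order_invariance(self):
        objects = self.objects()
        shuffled = objects.sample(frac=1, random_state=0)
        pd.testing.assert_frame_equal(
            median_timecourse(objects), median_timecourse(shuffled)
        )
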