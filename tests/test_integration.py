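"""DEG classification, trend matching, network, filters, ranking."""

import numpy as np
import pandas as pd
import pytest

from seasonomics.exceptions import InsufficientDataError, ValidationError
from seasonomics.integration import (
    apply_contrast_filters,
    build_correlation_network,
    deg_epigenome_classification,
    global_layer_correlations,
    intersect_and_rank,
    trend_match_structural_genes,
)
from seasonomics.intervals import GenomicInterval
from seasonomics.io_formats import GeneModel
from seasonomics.transcriptomics import normalize_expression


def gene(gid, start, tf=None, chrom="chr1", strand="+"):
    return GeneModel(gid, GenomicInterval(chrom, start, start + 1000, strand), tf)


def dar_frame(rows):
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "log2fc", "direction"])
    df["peak_name"] = [f"p{i}" for i in range(len(df))]
    df["comparison"] = ""
    df["p"] = 0.001
    df["is_dar"] = True
    return df


class TestDegClassification:
    def _genes(self, n=10, spacing=20_000):
        return [gene(f"g{i}", 10_000 + i * spacing) for i in range(n)]

    def test_hand_constructed_fractions(self):
        genes = self._genes()
        degs = {g.gene_id for g in genes}
        # DARs overlapping the bodies of g0, g1, g2 only
        dars = dar_frame(
            [("chr1", 10_000 + i * 20_000, 10_400 + i * 20_000, 1.0, "gain") for i in range(3)]
        )
        comp = pd.DataFrame(
            {"SPS": ["A"] * 10, "SUS": ["A"] * 10, "AUS": ["A"] * 10},
            index=[g.gene_id for g in genes],
        )
        summary, fractions = deg_epigenome_classification(degs, [dars], [], comp, genes)
        assert fractions["frac_dar"] == pytest.approx(0.3)
        assert fractions["frac_dmr"] == 0
        assert fractions["frac_switch"] == 0
        assert fractions["n_dual_evidence"] == 0

    def test_no_features_all_zero(self):
        genes = self._genes(5)
        degs = {g.gene_id for g in genes}
        comp = pd.DataFrame(
            {"SPS": ["B"] * 5, "SUS": ["B"] * 5, "AUS": ["B"] * 5},
            index=[g.gene_id for g in genes],
        )
        _, fractions = deg_epigenome_classification(degs, [], [], comp, genes)
        assert fractions["frac_dar"] == 0 and fractions["frac_dmr"] == 0

    def test_order_invariance(self):
        genes = self._genes()
        degs = [g.gene_id for g in genes]
        dars = dar_frame([("chr1", 10_000, 10_400, 1.0, "gain")])
        comp = pd.DataFrame(
            {"SPS": ["A"] * 10, "SUS": ["B"] * 10, "AUS": ["A"] * 10},
            index=degs,
        )
        _, f1 = deg_epigenome_classification(set(degs), [dars], [], comp, genes)
        _, f2 = deg_epigenome_classification(set(reversed(degs)), [dars], [], comp, genes)
        assert f1 == f2

    def test_empty_deg_set_rejected(self):
        with pytest.raises(ValidationError):
            deg_epigenome_classification(set(), [], [], pd.DataFrame(), [])


class TestTrendMatch:
    def test_planted_structural_genes_matched(self, default_dataset, screen_results):
        matched = screen_results["trend_matched"]
        assert matched == set(default_dataset.manifest.structural_genes)

    def test_flat_gene_excluded(self):
        patterns = pd.Series({"g1": "high-low-high", "g2": "flat"})
        summary = pd.DataFrame(
            {"has_dar": [True, True], "has_dmr": [False, False], "has_switch": [False, False]},
            index=["g1", "g2"],
        )
        assert trend_match_structural_genes(["g1", "g2"], patterns, summary) == {"g1"}

    def test_requires_epigenomic_evidence(self):
        patterns = pd.Series({"g1": "high-low-high"})
        summary = pd.DataFrame(
            {"has_dar": [False], "has_dmr": [False], "has_switch": [False]}, index=["g1"]
        )
        assert trend_match_structural_genes(["g1"], patterns, summary) == set()

    def test_empty_pathway_rejected(self):
        with pytest.raises(ValidationError):
            trend_match_structural_genes([], pd.Series(dtype=object), pd.DataFrame())


def expr_from_matrix(mat, genes):
    names = [f"{s}_{r}" for s in ("SPS", "SUS", "AUS") for r in (1, 2, 3)]
    samples = pd.DataFrame(
        {"season": [n.split("_")[0] for n in names],
         "replicate": [int(n.split("_")[1]) for n in names]},
        index=names,
    )
    counts = pd.DataFrame(mat, index=genes, columns=names)
    return normalize_expression(counts, pd.Series(1000.0, index=genes), samples)


class TestCorrelationNetwork:
    def test_identical_and_negated_profiles(self):
        base = np.array([10, 20, 40, 80, 160, 320, 640, 1280, 2560])
        mat = np.vstack([base, base, base[::-1], np.full(9, 50)])
        expr = expr_from_matrix(mat, ["target", "tf_same", "tf_anti", "tf_flat"])
        edges = build_correlation_network(expr, ["tf_same", "tf_anti"], ["target"])
        r = edges.set_index("tf_id")["r"]
        assert r["tf_same"] == pytest.approx(1.0, abs=1e-6)
        assert r["tf_anti"] < -0.8  # kept by the |r| criterion

    def test_pearson_matches_textbook_formula(self):
        rng = np.random.default_rng(0)
        mat = rng.integers(10, 1000, (2, 9))
        expr = expr_from_matrix(mat, ["target", "tf"])
        edges = build_correlation_network(expr, ["tf"], ["target"], r_thresh=-1.0)
        lc = expr.log2_cpm()
        x, y = lc.loc["tf"].values, lc.loc["target"].values
        xm, ym = x - x.mean(), y - y.mean()
        r_hand = (xm * ym).sum() / np.sqrt((xm**2).sum() * (ym**2).sum())
        assert edges["r"].iloc[0] == pytest.approx(r_hand)

    def test_zero_variance_tf_skipped_with_warning(self):
        # identical columns: size factors are all 1, so log2-CPM rows are flat
        mat = np.vstack([np.full(9, 100), np.full(9, 7)])
        expr = expr_from_matrix(mat, ["target", "tf_flat"])
        with pytest.warns(UserWarning, match="zero expression variance"):
            edges = build_correlation_network(expr, ["tf_flat"], ["target"])
        assert edges.empty

    def test_too_few_samples_rejected(self):
        counts = pd.DataFrame({"s1": [1, 2], "s2": [3, 4]}, index=["a", "b"])
        samples = pd.DataFrame({"season": ["SPS", "SUS"], "replicate": [1, 1]},
                               index=["s1", "s2"])
        expr = normalize_expression(counts, pd.Series(1000.0, index=["a", "b"]), samples)
        with pytest.raises(InsufficientDataError):
            build_correlation_network(expr, ["a"], ["b"])


class TestContrastFilters:
    def test_planted_master_passes_all_four(self, default_dataset, screen_results):
        flags = screen_results["flags"]
        row = flags.loc[default_dataset.manifest.master_tf]
        assert bool(row["expr_contrast"])
        assert bool(row["atac_contrast"])
        assert bool(row["meth_contrast"])
        assert bool(row["compartment_A_stable"])

    def test_negative_regulator_fails_expression_contrast(self, default_dataset, screen_results):
        flags = screen_results["flags"]
        assert not flags.loc[default_dataset.manifest.negative_tf, "expr_contrast"]

    def test_missing_layer_reported_as_missing(self):
        genes = [gene("tf1", 5000, tf="MYB")]
        flags = apply_contrast_filters(["tf1"], None, None, None, None, genes)
        assert flags.loc["tf1", ["expr_contrast", "atac_contrast", "meth_contrast"]].isna().all()

    def test_tf_without_promoter_peak_noted(self):
        genes = [gene("tf1", 500_000, tf="MYB")]
        empty_dar = dar_frame([("chr1", 0, 100, 1.0, "gain")])
        dars = {"SPS_vs_SUS": empty_dar, "SUS_vs_AUS": empty_dar}
        from seasonomics.io_formats import Peak

        distant_peak = Peak(GenomicInterval("chr1", 0, 100), name="p0")
        flags = apply_contrast_filters(
            ["tf1"], None, dars, None, None, genes, peaks=[distant_peak]
        )
        assert flags.loc["tf1", "atac_contrast"] is False or not flags.loc["tf1", "atac_contrast"]
        assert "no promoter peak" in flags.loc["tf1", "note"]


class TestIntersectAndRank:
    def _edges(self, tfs, r=0.9):
        return pd.DataFrame(
            {"tf_id": tfs, "target_id": "t", "r": r, "n_samples": 9}
        )

    def _flags(self, rows):
        return pd.DataFrame(
            rows,
            columns=["expr_contrast", "atac_contrast", "meth_contrast",
                     "compartment_A_stable"],
        ).assign(note="")

    def test_single_tf_all_layers_rank_one(self):
        flags = self._flags([[True, True, True, True]]).set_axis(["tf1"])
        report = intersect_and_rank(self._edges(["tf1"]), flags)
        assert report.top_candidate == "tf1"
        assert report.table.loc["tf1", "n_layers_passed"] == 4
        assert report.layer_counts == {
            "expr_contrast": 1, "atac_contrast": 1, "meth_contrast": 1,
            "compartment_A_stable": 1,
        }

    def test_deterministic_tiebreak_by_id(self):
        flags = self._flags([[True, False, False, False]] * 2).set_axis(["tfB", "tfA"])
        report = intersect_and_rank(self._edges(["tfB", "tfA"]), flags)
        assert list(report.table.index) == ["tfA", "tfB"]

    def test_layer_counts_bound_intersection(self, screen_results):
        report = screen_results["report"]
        n_all = int((report.table["n_layers_passed"] == 4).sum())
        assert n_all <= min(report.layer_counts.values())

    def test_planted_master_unique_all_layer_candidate(self, default_dataset, screen_results):
        report = screen_results["report"]
        all_four = list(report.table.index[report.table["n_layers_passed"] == 4])
        assert all_four == [default_dataset.manifest.master_tf]
        assert report.table["rank"].iloc[0] == 1

    def test_empty_edges_empty_report(self):
        with pytest.warns(UserWarning):
            report = intersect_and_rank(
                pd.DataFrame(columns=["tf_id", "target_id", "r", "n_samples"]),
                self._flags([]),
            )
        assert report.table.empty


class TestGlobalLayerCorrelations:
    def test_proportional_accessibility_positive(self):
        rng = np.random.default_rng(1)
        expr = pd.Series(rng.normal(0, 1, 50), index=[f"g{i}" for i in range(50)])
        out = global_layer_correlations(expr, expr * 2.0, -expr + 0.1)
        assert out["expression_accessibility"]["rho"] == pytest.approx(1.0)
        assert out["expression_methylation"]["rho"] == pytest.approx(-1.0)

    def test_too_few_genes_rejected(self):
        s = pd.Series([1.0] * 5, index=list("abcde"))
        with pytest.raises(InsufficientDataError):
            global_layer_correlations(s, s, s)

    def test_default_run_signs(self, screen_results):
        corr = screen_results["layer_correlations"]
        assert corr["expression_accessibility"]["rho"] > 0
        assert corr["expression_accessibility"]["ci_low"] > 0
        assert corr["expression_methylation"]["rho"] < 0
        assert corr["expression_methylation"]["ci_high"] < 0
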