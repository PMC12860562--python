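"""ATAC annotation/DARs/overlap and WGBS levels/DMRs/profiles."""

import numpy as np
import pandas as pd
import pytest

from seasonomics.epigenomics import (
    annotate_peaks_to_genes,
    call_dars,
    call_dmrs,
    classify_dmr_direction,
    methylation_level_by_context,
    methylation_profile_around_summits,
    replicate_overlap,
    tss_enrichment_profile,
)
from seasonomics.exceptions import InsufficientDataError, ValidationError
from seasonomics.intervals import GenomicInterval, promoter_interval
from seasonomics.io_formats import GeneModel, MethylationSiteTable, Peak
from seasonomics.synthetic import simulate_dmr_benchmark


def gene(gid, chrom, start, end, strand="+", tf=None):
    return GeneModel(gid, GenomicInterval(chrom, start, end, strand), tf)


def peak(chrom, start, end, name="p"):
    return Peak(GenomicInterval(chrom, start, end), name=name)


class TestAnnotatePeaks:
    def test_peak_on_tss_is_promoter(self):
        genes = [gene("g1", "chr1", 5000, 7000)]
        hits = annotate_peaks_to_genes([peak("chr1", 4900, 5100)], genes)
        assert hits.loc[0, "gene_id"] == "g1"
        assert hits.loc[0, "category"] == "promoter"

    def test_far_peak_is_distal(self):
        genes = [gene("g1", "chr1", 50_000, 52_000)]
        hits = annotate_peaks_to_genes([peak("chr1", 10_000, 10_400)], genes)
        assert hits.loc[0, "category"] == "distal"
        assert hits.loc[0, "gene_id"] is None

    def test_matches_brute_force_all_pairs(self):
        rng = np.random.default_rng(0)
        genes = []
        for i in range(1000):
            start = int(rng.integers(10_000, 5_000_000))
            genes.append(
                gene(f"g{i}", f"chr{rng.integers(1, 4)}", start, start + 1500,
                     "+" if rng.random() < 0.5 else "-")
            )
        peaks = []
        for i in range(1000):
            start = int(rng.integers(0, 5_000_000))
            peaks.append(peak(f"chr{rng.integers(1, 4)}", start, start + int(rng.integers(100, 800)), f"p{i}"))
        hits = annotate_peaks_to_genes(peaks, genes, upstream=3000, downstream=3000)
        got = {
            (row.peak_name, row.gene_id)
            for row in hits.itertuples()
            if row.category == "promoter"
        }
        expected = set()
        for p in peaks:
            for g in genes:
                window = promoter_interval(g.tss, g.strand, g.chrom, 3000, 3000)
                if p.interval.overlaps(window):
                    expected.add((p.name, g.gene_id))
        assert got == expected

    def test_negative_window_rejected(self):
        with pytest.raises(ValidationError):
            annotate_peaks_to_genes([], [], upstream=-1)


class TestTssProfile:
    def test_uniform_coverage_flat(self):
        coverage = {"chr1": np.full(10_000, 2.0)}
        genes = [gene("g1", "chr1", 5000, 6000)]
        profile = tss_enrichment_profile(coverage, genes, flank=100)
        np.testing.assert_allclose(profile, 2.0)
        assert len(profile) == 201

    def test_gaussian_bump_peaks_at_center(self):
        x = np.arange(10_000)
        coverage = {"chr1": 1 + 5 * np.exp(-((x - 5000) ** 2) / (2 * 50**2))}
        genes = [gene("g1", "chr1", 5000, 6000)]
        profile = tss_enrichment_profile(coverage, genes, flank=300)
        assert np.argmax(profile) == 300

    def test_strand_reversal_invariant_for_symmetric_coverage(self):
        x = np.arange(10_000)
        coverage = {"chr1": 1 + np.exp(-((x - 5000) ** 2) / (2 * 80**2))}
        fwd = [gene("g1", "chr1", 5000, 6000, "+")]
        rev = [gene("g1", "chr1", 4000, 5001, "-")]  # TSS also at 5000
        pf = tss_enrichment_profile(coverage, fwd, flank=200)
        pr = tss_enrichment_profile(coverage, rev, flank=200)
        np.testing.assert_allclose(pf, pr, rtol=1e-9)

    def test_empty_tss_list_errors(self):
        with pytest.raises(InsufficientDataError):
            tss_enrichment_profile({"chr1": np.ones(100)}, [], flank=10)


def _atac_setup(counts):
    peaks = [peak("chr1", 1000 * i, 1000 * i + 400, f"p{i}") for i in range(len(counts))]
    names = [f"{s}_{r}" for s in ("SPS", "SUS") for r in (1, 2, 3)]
    df = pd.DataFrame(counts, index=[p.name for p in peaks], columns=names)
    samples = pd.DataFrame(
        {"season": [n.split("_")[0] for n in names],
         "replicate": [int(n.split("_")[1]) for n in names]},
        index=names,
    )
    return peaks, df, samples


class TestCallDars:
    def test_identical_matrices_no_dars(self):
        rng = np.random.default_rng(1)
        block = rng.integers(50, 500, (40, 3))
        peaks, counts, samples = _atac_setup(np.hstack([block, block]))
        res = call_dars(peaks, counts, samples, "SPS", "SUS")
        assert not res["is_dar"].any()

    def test_planted_gain_called(self):
        rng = np.random.default_rng(2)
        base = rng.integers(200, 400, (30, 1)).astype(float)
        a = base * np.exp(rng.normal(0, 0.03, (30, 3)))
        b = base * np.exp(rng.normal(0, 0.03, (30, 3)))
        b[0] *= 2.0  # true log2fc = 1.0
        peaks, counts, samples = _atac_setup(np.hstack([a, b]).astype(int))
        res = call_dars(peaks, counts, samples, "SPS", "SUS")
        assert bool(res.loc[0, "is_dar"])
        assert res.loc[0, "direction"] == "gain"

    def test_small_effect_significant_but_below_lfc_bound(self):
        a = np.array([[1000, 1001, 999]] * 20, dtype=float)
        b = a * 2**0.4  # highly significant, |lfc| < 0.58
        peaks, counts, samples = _atac_setup(np.hstack([a, b]).astype(int))
        res = call_dars(peaks, counts, samples, "SPS", "SUS")
        assert (res["p"] < 1e-3).all()
        assert not res["is_dar"].any()

    def test_antisymmetric_under_season_swap(self):
        rng = np.random.default_rng(3)
        peaks, counts, samples = _atac_setup(rng.integers(50, 800, (40, 6)))
        ab = call_dars(peaks, counts, samples, "SPS", "SUS")
        ba = call_dars(peaks, counts, samples, "SUS", "SPS")
        np.testing.assert_allclose(ab["log2fc"], -ba["log2fc"])
        called = ab["is_dar"]
        assert (ab.loc[called, "direction"] != ba.loc[called, "direction"]).all()

    def test_empty_consensus_rejected(self):
        with pytest.raises(ValidationError):
            call_dars([], pd.DataFrame(), pd.DataFrame(), "SPS", "SUS")


class TestReplicateOverlap:
    def test_identical_sets_all_shared(self):
        ivs = [GenomicInterval("chr1", i * 100, i * 100 + 50) for i in range(20)]
        res = replicate_overlap(ivs, list(ivs))
        assert res.a_shared == res.b_shared == 20
        assert res.a_only == res.b_only == 0

    def test_disjoint_sets_zero_shared(self):
        a = [GenomicInterval("chr1", 0, 10)]
        b = [GenomicInterval("chr1", 100, 110)]
        res = replicate_overlap(a, b)
        assert res.a_shared == 0 and res.b_only == 1

    def test_counts_match_brute_force(self):
        rng = np.random.default_rng(4)

        def random_set(n):
            out = []
            for _ in range(n):
                s = int(rng.integers(0, 100_000))
                out.append(GenomicInterval(f"chr{rng.integers(1, 3)}", s, s + int(rng.integers(50, 500))))
            return out

        a, b = random_set(300), random_set(300)
        res = replicate_overlap(a, b)
        brute_a = sum(1 for x in a if any(x.overlaps(y) for y in b))
        brute_b = sum(1 for y in b if any(y.overlaps(x) for x in a))
        assert (res.a_shared, res.b_shared) == (brute_a, brute_b)


def meth_table(rows):
    df = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "context", "meth", "total"])
    return MethylationSiteTable(df)


class TestMethylationLevel:
    def test_uniform_sites(self):
        t = meth_table([("chr1", i, "+", c, 5, 10) for i in range(6) for c in ("CG", "CHG")])
        levels = methylation_level_by_context(t)
        assert levels == {"CG": pytest.approx(0.5), "CHG": pytest.approx(0.5)}

    def test_coverage_weighting(self):
        t = meth_table([("chr1", 1, "+", "CG", 9, 10), ("chr1", 2, "+", "CG", 1, 10)])
        assert methylation_level_by_context(t)["CG"] == pytest.approx(0.5)

    def test_region_without_sites_missing(self):
        t = meth_table([("chr1", 1, "+", "CG", 5, 10)])
        levels = methylation_level_by_context(t, regions=[GenomicInterval("chr2", 0, 100)])
        assert levels == {}

    def test_whole_genome_restriction_equals_unrestricted(self):
        rng = np.random.default_rng(5)
        rows = [
            ("chr1", int(p), "+", "CG", int(m), int(m) + 3)
            for p, m in zip(rng.integers(0, 10_000, 200), rng.integers(0, 10, 200))
        ]
        t = meth_table(rows)
        full = methylation_level_by_context(t)
        restricted = methylation_level_by_context(t, regions=[GenomicInterval("chr1", 0, 10_001)])
        assert full == restricted


class TestCallDmrs:
    def test_identical_samples_no_dmrs(self):
        rng = np.random.default_rng(6)
        rows = [
            ("chr1", int(p), "+", "CG", int(m), 30)
            for p, m in zip(np.sort(rng.integers(0, 20_000, 800)), rng.integers(5, 25, 800))
        ]
        t = meth_table(rows)
        assert call_dmrs(t, t, "CG") == []

    def test_planted_region_recovered_merged_hyper(self):
        a, b, truth = simulate_dmr_benchmark(
            seed=1, n_regions=1, chrom_length=50_000, spacing=8
        )
        # region is 0.8 in A and 0.2 in B: hypo B-vs-A; swap for hyper
        dmrs = call_dmrs(b, a, "CG", chrom_lengths={"chr1": 50_000})
        assert len(dmrs) == 1
        d = dmrs[0]
        assert d.direction == "hyper"
        assert d.interval.overlaps(truth[0])
        assert d.level_b > 0.6 and d.level_a < 0.4

    def test_sparse_windows_never_called(self):
        # 4 sites in one window with min_sites=5: excluded from testing
        rows_a = [("chr1", p, "+", "CG", 28, 30) for p in (10, 30, 50, 70)]
        rows_b = [("chr1", p, "+", "CG", 2, 30) for p in (10, 30, 50, 70)]
        assert call_dmrs(meth_table(rows_a), meth_table(rows_b), "CG",
                         chrom_lengths={"chr1": 200}) == []

    def test_merged_dmrs_never_overlap(self):
        a, b, _ = simulate_dmr_benchmark(seed=2)
        dmrs = call_dmrs(a, b, "CG", chrom_lengths={"chr1": 200_000})
        dmrs = sorted(dmrs, key=lambda d: d.interval.start)
        for x, y in zip(dmrs, dmrs[1:]):
            assert x.interval.end <= y.interval.start

    def test_unknown_context_rejected(self):
        t = meth_table([("chr1", 1, "+", "CG", 1, 2)])
        with pytest.raises(ValidationError):
            call_dmrs(t, t, "CpG")


class TestDmrDirectionTally:
    def test_tally_matches_brute_force(self):
        a, b, _ = simulate_dmr_benchmark(seed=3)
        dmrs = call_dmrs(a, b, "CG", chrom_lengths={"chr1": 200_000})
        counts = classify_dmr_direction(dmrs)
        brute = {"hyper": 0, "hypo": 0}
        for d in dmrs:
            brute["hyper" if d.level_b > d.level_a else "hypo"] += 1
        assert counts == brute
        assert counts["hyper"] + counts["hypo"] == len(dmrs)

    def test_empty_list(self):
        assert classify_dmr_direction([]) == {"hyper": 0, "hypo": 0}


class TestSummitProfiles:
    def test_uniform_methylation_flat_profile(self):
        rng = np.random.default_rng(7)
        pos = np.sort(rng.integers(0, 50_000, 3000))
        rows = [("chr1", int(p), "+", "CG", 6, 12) for p in pos]
        t = meth_table(rows)
        profile = methylation_profile_around_summits(t, [("chr1", 25_000)], flank=1000, bin_size=50)
        np.testing.assert_allclose(profile["CG"].dropna(), 0.5)

    def test_profile_length(self):
        t = meth_table([("chr1", 500, "+", "CG", 1, 2)])
        profile = methylation_profile_around_summits(t, [("chr1", 500)], flank=1000, bin_size=50)
        assert len(profile) == 2 * 1000 // 50 + 1

    def test_planted_dip_minimum_at_center(self, default_dataset):
        ds = default_dataset
        summits = [(p.chrom, p.summit) for p in ds.peaks if p.summit is not None]
        profile = methylation_profile_around_summits(
            ds.methylation["SPS_1"], summits, flank=1000, bin_size=50
        )
        for ctx in ("CG", "CHG", "CHH"):
            series = profile[ctx]
            center = series.loc[0]
            edges = (series.iloc[:4].mean() + series.iloc[-4:].mean()) / 2
            assert center < edges
            assert abs(series.idxmin()) <= 150

    def test_no_sites_in_range_errors(self):
        t = meth_table([("chr1", 1, "+", "CG", 1, 2)])
        with pytest.raises(InsufficientDataError):
            methylation_profile_around_summits(t, [("chr2", 5000)], flank=100)
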