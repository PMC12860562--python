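"""ATAC and WGBS layers.

ATAC: peak-to-gene promoter annotation, TSS enrichment profiles,
differential accessibility (DAR) calling over a consensus peak set, and
replicate-overlap summaries.

WGBS: context-resolved methylation levels (CG/CHG/CHH, coverage weighted),
a transparent sliding-window DMR caller (window statistics on pooled counts,
BH correction, merge of adjacent significant windows), hyper/hypo
classification, and methylation profiles around peak summits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import CONTEXTS
from .exceptions import (
    InsufficientDataError,
    ValidationError,
)
from .intervals import GenomicInterval, IntervalIndex, promoter_interval
from .io_formats import GeneModel, MethylationSiteTable, Peak

# ---------------------------------------------------------------------------
# ATAC: annotation, profiles, DARs, overlap


def annotate_peaks_to_genes(
    peaks: Sequence[Peak],
    genes: Sequence[GeneModel],
    upstream: int = 3000,
    downstream: int = 3000,
) -> pd.DataFrame:
    """Assign peaks to gene promoters by strand-aware window overlap.

    A peak is promoter-assigned to every gene whose window
    [tss - upstream, tss + downstream] (oriented along the gene's strand)
    it overlaps by >= 1 bp; peaks hitting no window are labelled distal.
    Returns one row per (peak, gene) hit plus one row per distal peak.
    """
    if upstream < 0 or downstream < 0:
        raise ValidationError("promoter window sizes must be non-negative")
    promoters = [
        promoter_interval(g.tss, g.strand, g.chrom, upstream, downstream)
        for g in genes
    ]
    index = IntervalIndex(promoters)
    rows = []
    for pi, peak in enumerate(peaks):
        hits = index.overlapping(peak.interval)
        if hits:
            for gi in hits:
                rows.append((pi, peak.name, genes[gi].gene_id, "promoter"))
        else:
            rows.append((pi, peak.name, None, "distal"))
    return pd.DataFrame(rows, columns=["peak_index", "peak_name", "gene_id", "category"])


def genes_with_promoter_peak(assignments: pd.DataFrame) -> set[str]:
    mask = assignments["category"] == "promoter"
    return set(assignments.loc[mask, "gene_id"])


def tss_enrichment_profile(
    coverage: Mapping[str, np.ndarray],
    genes: Sequence[GeneModel],
    flank: int,
) -> np.ndarray:
    """Strand-oriented mean per-bp coverage over [-flank, +flank] around TSS.

    Genes whose flank extends past a chromosome end are skipped; the profile
    has length ``2 * flank + 1`` with the TSS at the center.
    """
    if flank <= 0:
        raise ValidationError("flank must be positive")
    if not genes:
        raise InsufficientDataError("empty TSS list")
    acc = np.zeros(2 * flank + 1)
    n = 0
    for g in genes:
        cov = coverage.get(g.chrom)
        if cov is None:
            continue
        lo, hi = g.tss - flank, g.tss + flank + 1
        if lo < 0 or hi > len(cov):
            continue
        window = cov[lo:hi]
        if g.strand == "-":
            window = window[::-1]
        acc += window
        n += 1
    if n == 0:
        raise InsufficientDataError("no TSS with full flanking coverage")
    return acc / n


def call_dars(
    peaks: Sequence[Peak],
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    season_a: str,
    season_b: str,
    *,
    lfc_thresh: float = 0.58,
    p_thresh: float = 0.01,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Differential accessibility over a shared consensus peak set.

    Counts are library-size normalized to log2-CPM; each peak gets a Welch
    t-test between the two seasons. A peak is a DAR iff
    ``|log2fc| >= lfc_thresh`` (inclusive) and raw ``p <= p_thresh``
    (inclusive) -- raw p, not FDR. Direction is gain when season_b is more
    accessible than season_a.
    """
    if len(peaks) == 0 or counts.empty:
        raise ValidationError("empty consensus peak set")
    if len(peaks) != len(counts):
        raise ValidationError("peak list and count matrix differ in length")
    cols_a = list(samples.index[samples["season"] == season_a])
    cols_b = list(samples.index[samples["season"] == season_b])
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise InsufficientDataError("need >= 2 replicates per season")
    from .transcriptomics import median_of_ratios_size_factors

    lib = counts.sum(axis=0).astype(float)
    geo_lib = float(np.exp(np.log(lib.values).mean()))
    eff = median_of_ratios_size_factors(counts).values * geo_lib
    lc = np.log2(1e6 * (counts.values + pseudocount) / eff[None, :])
    lc = pd.DataFrame(lc, index=counts.index, columns=counts.columns)
    a, b = lc[cols_a].values, lc[cols_b].values
    log2fc = b.mean(axis=1) - a.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.asarray(stats.ttest_ind(a, b, axis=1, equal_var=False).pvalue)
    p[np.isnan(p)] = 1.0
    out = pd.DataFrame(
        {
            "chrom": [pk.interval.chrom for pk in peaks],
            "start": [pk.interval.start for pk in peaks],
            "end": [pk.interval.end for pk in peaks],
            "peak_name": [pk.name for pk in peaks],
            "comparison": f"{season_a}_vs_{season_b}",
            "log2fc": log2fc,
            "p": p,
        }
    )
    out["is_dar"] = (out["log2fc"].abs() >= lfc_thresh) & (out["p"] <= p_thresh)
    out["direction"] = np.where(out["log2fc"] > 0, "gain", "loss")
    return out


@dataclass(frozen=True)
class OverlapCounts:
    """Replicate-overlap summary (>= 1 bp reciprocal pairing)."""

    a_total: int
    b_total: int
    a_shared: int  # items of A overlapping >= 1 item of B
    b_shared: int

    @property
    def a_only(self) -> int:
        return self.a_total - self.a_shared

    @property
    def b_only(self) -> int:
        return self.b_total - self.b_shared


def replicate_overlap(
    intervals_a: Sequence[GenomicInterval], intervals_b: Sequence[GenomicInterval]
) -> OverlapCounts:
    """Count intervals private to each replicate and shared between them."""
    index_b = IntervalIndex(list(intervals_b))
    a_shared = sum(1 for iv in intervals_a if index_b.overlapping(iv))
    index_a = IntervalIndex(list(intervals_a))
    b_shared = sum(1 for iv in intervals_b if index_a.overlapping(iv))
    return OverlapCounts(len(intervals_a), len(intervals_b), a_shared, b_shared)


def peak_intervals(peaks: Iterable[Peak]) -> list[GenomicInterval]:
    return [p.interval for p in peaks]


# ---------------------------------------------------------------------------
# WGBS: levels, DMRs, profiles


def methylation_level_by_context(
    table: MethylationSiteTable,
    regions: Sequence[GenomicInterval] | None = None,
) -> dict[str, float]:
    """Coverage-weighted mean level per context.

    ``level = sum(meth) / sum(total)`` over sites of each context, optionally
    restricted to ``regions``. Contexts without any covered site are absent
    from the result (missing, not zero).
    """
    if len(table) == 0:
        raise ValidationError("empty methylation table")
    sites = table.sites
    if regions is not None:
        index = IntervalIndex(list(regions))
        keep = np.zeros(len(sites), dtype=bool)
        for chrom, grp in sites.groupby("chrom", sort=False):
            tree = index._trees.get(chrom)
            if tree is None:
                continue
            pos = grp["pos"].values
            mask = np.fromiter(
                (bool(tree.overlap(p, p + 1)) for p in pos), bool, len(pos)
            )
            keep[grp.index.values] = mask
        sites = sites[keep]
    out: dict[str, float] = {}
    for context in CONTEXTS:
        sub = sites[sites["context"] == context]
        total = int(sub["total"].sum())
        if len(sub) == 0 or total == 0:
            continue
        out[context] = float(sub["meth"].sum()) / total
    return out


@dataclass(frozen=True)
class DMR:
    """A differentially methylated region (direction of B relative to A)."""

    interval: GenomicInterval
    context: str
    level_a: float
    level_b: float
    q: float
    n_sites: int

    @property
    def direction(self) -> str:
        return "hyper" if self.level_b > self.level_a else "hypo"


def _chi2_pooled(ma, ua, mb, ub) -> np.ndarray:
    """Vectorized 1-df Pearson chi-square p for pooled 2x2 count tables."""
    ma, ua, mb, ub = (np.asarray(x, dtype=float) for x in (ma, ua, mb, ub))
    n = ma + ua + mb + ub
    r1, r2 = ma + ua, mb + ub
    c1, c2 = ma + mb, ua + ub
    denom = r1 * r2 * c1 * c2
    with np.errstate(invalid="ignore", divide="ignore"):
        stat = n * (ma * ub - mb * ua) ** 2 / denom
    stat = np.where(denom > 0, stat, 0.0)
    return stats.chi2.sf(stat, df=1)


def call_dmrs(
    sites_a: MethylationSiteTable,
    sites_b: MethylationSiteTable,
    context: str,
    *,
    window: int = 100,
    step: int = 50,
    min_sites: int = 5,
    delta: float | None = None,
    q_thresh: float = 0.05,
    min_coverage: int = 4,
    min_windows: int = 2,
    chrom_lengths: Mapping[str, int] | None = None,
) -> list[DMR]:
    """Sliding-window DMR caller on pooled cytosine counts.

    Sites of the requested context covered by >= ``min_coverage`` reads in
    both samples are matched by position. Windows of ``window`` bp advanced
    by ``step`` with >= ``min_sites`` shared sites are tested by a pooled
    2x2 chi-square; BH correction runs over all tested windows. A window is
    called when the absolute level difference (B - A) is >= ``delta`` and
    q < ``q_thresh``; overlapping or adjacent called windows are merged and
    levels recomputed over the merged span. A merged region is reported
    only when supported by >= ``min_windows`` called windows (isolated
    single-window calls at moderate coverage are dominated by sampling
    noise). Merged DMRs never overlap.
    """
    if context not in CONTEXTS:
        raise ValidationError(f"unknown context {context!r}")
    if delta is None:
        delta = 0.05 if context == "CHH" else 0.1
    a = sites_a.for_context(context)
    b = sites_b.for_context(context)
    merged = a.merge(
        b, on=["chrom", "pos"], suffixes=("_a", "_b"), how="inner", sort=True
    )
    merged = merged[
        (merged["total_a"] >= min_coverage) & (merged["total_b"] >= min_coverage)
    ]
    if merged.empty:
        return []

    win_rows = []  # (chrom, start, end, ma, ta, mb, tb, n_sites)
    for chrom, grp in merged.groupby("chrom", sort=True):
        pos = grp["pos"].values
        order = np.argsort(pos, kind="stable")
        pos = pos[order]
        ma = grp["meth_a"].values[order].astype(np.int64)
        ta = grp["total_a"].values[order].astype(np.int64)
        mb = grp["meth_b"].values[order].astype(np.int64)
        tb = grp["total_b"].values[order].astype(np.int64)
        cma, cta = np.concatenate([[0], np.cumsum(ma)]), np.concatenate([[0], np.cumsum(ta)])
        cmb, ctb = np.concatenate([[0], np.cumsum(mb)]), np.concatenate([[0], np.cumsum(tb)])
        length = (
            chrom_lengths[chrom]
            if chrom_lengths is not None
            else int(pos[-1]) + 1
        )
        starts = np.arange(0, max(length - window, 0) + 1, step, dtype=np.int64)
        lo = np.searchsorted(pos, starts, side="left")
        hi = np.searchsorted(pos, starts + window, side="left")
        n_sites = hi - lo
        keep = n_sites >= min_sites
        if not keep.any():
            continue
        s, l_, h = starts[keep], lo[keep], hi[keep]
        win_rows.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": s,
                    "end": s + window,
                    "ma": cma[h] - cma[l_],
                    "ta": cta[h] - cta[l_],
                    "mb": cmb[h] - cmb[l_],
                    "tb": ctb[h] - ctb[l_],
                    "n_sites": n_sites[keep],
                }
            )
        )
    if not win_rows:
        return []
    windows = pd.concat(win_rows, ignore_index=True)
    level_a = windows["ma"] / windows["ta"]
    level_b = windows["mb"] / windows["tb"]
    diff = level_b - level_a
    p = _chi2_pooled(windows["ma"], windows["ta"] - windows["ma"],
                     windows["mb"], windows["tb"] - windows["mb"])
    q = multipletests(p, method="fdr_bh")[1]
    called = (np.abs(diff) >= delta) & (q < q_thresh)
    windows = windows.assign(q=q, called=called)

    # merge overlapping/adjacent called windows, recompute levels per span
    dmrs: list[DMR] = []
    site_lookup = {
        chrom: grp.sort_values("pos") for chrom, grp in merged.groupby("chrom")
    }
    for chrom, grp in windows[windows["called"]].groupby("chrom", sort=True):
        grp = grp.sort_values("start")
        spans: list[list] = []  # [start, end, q_min, n_windows]
        for _, w in grp.iterrows():
            if spans and w["start"] <= spans[-1][1]:
                spans[-1][1] = max(spans[-1][1], int(w["end"]))
                spans[-1][2] = min(spans[-1][2], float(w["q"]))
                spans[-1][3] += 1
            else:
                spans.append([int(w["start"]), int(w["end"]), float(w["q"]), 1])
        sites = site_lookup[chrom]
        pos = sites["pos"].values
        for start, end, q_min, n_windows in spans:
            if n_windows < min_windows:
                continue
            lo, hi = np.searchsorted(pos, start), np.searchsorted(pos, end)
            block = sites.iloc[lo:hi]
            la = block["meth_a"].sum() / block["total_a"].sum()
            lb = block["meth_b"].sum() / block["total_b"].sum()
            dmrs.append(
                DMR(
                    GenomicInterval(chrom, start, end),
                    context,
                    float(la),
                    float(lb),
                    q_min,
                    int(hi - lo),
                )
            )
    return dmrs


def classify_dmr_direction(dmrs: Sequence[DMR]) -> dict[str, int]:
    """Partition DMRs into hyper/hypo counts; hyper + hypo == total."""
    counts = {"hyper": 0, "hypo": 0}
    for d in dmrs:
        counts[d.direction] += 1
    return counts


def methylation_profile_around_summits(
    table: MethylationSiteTable,
    summits: Sequence[tuple[str, int]],
    flank: int = 1000,
    bin_size: int = 50,
) -> pd.DataFrame:
    """Binned coverage-weighted methylation level per context around summits.

    Returns a DataFrame with ``2 * flank // bin_size + 1`` rows indexed by
    bin-center offset and one column per context present; entries are
    sum(meth)/sum(total) pooled over all summits per offset bin (NaN where
    no site falls in a bin).
    """
    if flank <= 0 or bin_size <= 0:
        raise ValidationError("flank and bin size must be positive")
    n_bins = 2 * flank // bin_size + 1
    centers = (np.arange(n_bins) - n_bins // 2) * bin_size
    sites = table.sites
    meth_acc = {c: np.zeros(n_bins) for c in CONTEXTS}
    total_acc = {c: np.zeros(n_bins) for c in CONTEXTS}
    by_chrom = {chrom: grp.sort_values("pos") for chrom, grp in sites.groupby("chrom")}
    for chrom, summit in summits:
        grp = by_chrom.get(chrom)
        if grp is None:
            continue
        pos = grp["pos"].values
        lo = np.searchsorted(pos, summit - flank)
        hi = np.searchsorted(pos, summit + flank + 1)
        block = grp.iloc[lo:hi]
        offsets = block["pos"].values - summit
        bins = np.clip((offsets + flank + bin_size // 2) // bin_size, 0, n_bins - 1)
        for context in CONTEXTS:
            mask = (block["context"] == context).values
            if not mask.any():
                continue
            np.add.at(meth_acc[context], bins[mask], block["meth"].values[mask])
            np.add.at(total_acc[context], bins[mask], block["total"].values[mask])
    cols = {}
    for context in CONTEXTS:
        with np.errstate(invalid="ignore", divide="ignore"):
            level = meth_acc[context] / total_acc[context]
        if np.isfinite(level).any():
            cols[context] = level
    if not cols:
        raise InsufficientDataError("no summit has any methylation site in range")
    return pd.DataFrame(cols, index=pd.Index(centers, name="offset"))
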