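"""Multi-omics integration: DEG-by-epigenome classification, trend-matched
structural genes, the TF correlation network, the four contrasting-pattern
filters, intersection ranking, and global layer-correlation summaries.

The candidate screen asks, for every TF correlated with an anthocyanin
structural gene (|r| above threshold), whether it shows the four-layer
summer-contrast signature: expression down then up across SPS->SUS->AUS,
promoter accessibility lost then gained, promoter methylation peaking in
summer, and A-compartment residence in all three seasons. TFs are ranked by
the number of layers passed, with deterministic tie-breaking.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import SEASONS, ConfigBundle
from .epigenomics import DMR, call_dars, call_dmrs
from .exceptions import InsufficientDataError, ValidationError
from .intervals import GenomicInterval, IntervalIndex, promoter_interval
from .io_formats import GeneModel, MethylationSiteTable, Peak
from .transcriptomics import SeasonalExpression, classify_seasonal_pattern, differential_expression

log = logging.getLogger(__name__)

COMPARISONS = (("SPS", "SUS"), ("SUS", "AUS"))


def _comparison_key(a: str, b: str) -> str:
    return f"{a}_vs_{b}"


def _gene_regions(
    genes: Sequence[GeneModel], upstream: int, downstream: int
) -> dict[str, list[GenomicInterval]]:
    """Gene body plus strand-aware promoter window, per gene."""
    out = {}
    for g in genes:
        out[g.gene_id] = [
            g.interval,
            promoter_interval(g.tss, g.strand, g.chrom, upstream, downstream),
        ]
    return out


def _regions_overlap_index(feature_intervals: Sequence[GenomicInterval]) -> IntervalIndex:
    return IntervalIndex(list(feature_intervals))


def _dar_intervals(dars: pd.DataFrame, only_called: bool = True) -> list[GenomicInterval]:
    df = dars[dars["is_dar"]] if only_called else dars
    return [
        GenomicInterval(c, int(s), int(e))
        for c, s, e in zip(df["chrom"], df["start"], df["end"])
    ]


def deg_epigenome_classification(
    degs: set[str],
    dars: Sequence[pd.DataFrame],
    dmrs: Sequence[DMR],
    gene_compartments: pd.DataFrame,
    genes: Sequence[GeneModel],
    *,
    promoter_upstream: int = 3000,
    promoter_downstream: int = 3000,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-DEG epigenomic evidence booleans and their fractions.

    A DEG has accessibility evidence when >= 1 called DAR overlaps its gene
    body or promoter; methylation evidence likewise from DMRs of any
    context; compartment evidence when its three-season label string is not
    constant (an A/B switch). Also reports the count of DEGs with both
    chromatin (DAR or switch) and methylation evidence.
    """
    if not degs:
        raise ValidationError("empty DEG set")
    gene_map = {g.gene_id: g for g in genes}
    missing = degs - set(gene_map)
    if missing:
        raise ValidationError(f"DEGs missing from annotation: {sorted(missing)[:5]}")
    dar_ivs = [iv for df in dars for iv in _dar_intervals(df)]
    dar_index = IntervalIndex(dar_ivs) if dar_ivs else None
    dmr_index = IntervalIndex([d.interval for d in dmrs]) if dmrs else None
    regions = _gene_regions(
        [gene_map[g] for g in sorted(degs)], promoter_upstream, promoter_downstream
    )
    rows = []
    for gid in sorted(degs):
        ivs = regions[gid]
        has_dar = bool(dar_index) and any(dar_index.overlapping(iv) for iv in ivs)
        has_dmr = bool(dmr_index) and any(dmr_index.overlapping(iv) for iv in ivs)
        labels = (
            gene_compartments.loc[gid, list(SEASONS)].tolist()
            if gid in gene_compartments.index
            else ["NaN"] * 3
        )
        clean = [x for x in labels if x != "NaN"]
        has_switch = len(set(clean)) > 1
        rows.append((gid, has_dar, has_dmr, has_switch, "2".join(labels)))
    summary = pd.DataFrame(
        rows, columns=["gene_id", "has_dar", "has_dmr", "has_switch", "switch"]
    ).set_index("gene_id")
    n = len(summary)
    fractions = {
        "frac_dar": summary["has_dar"].sum() / n,
        "frac_switch": summary["has_switch"].sum() / n,
        "frac_dmr": summary["has_dmr"].sum() / n,
        "n_dual_evidence": int(
            ((summary["has_dar"] | summary["has_switch"]) & summary["has_dmr"]).sum()
        ),
    }
    return summary, fractions


def trend_match_structural_genes(
    pathway_genes: Sequence[str],
    patterns: pd.Series,
    summary: pd.DataFrame,
    metabolite_trend: str = "high-low-high",
) -> set[str]:
    """Pathway genes matching the pigment trend with epigenomic support.

    A gene matches when its seasonal expression pattern equals the
    metabolite trend and it has >= 1 epigenomic evidence (DAR, DMR, or a
    compartment switch). The result is a subset of the pathway list.
    """
    if not pathway_genes:
        raise ValidationError("empty pathway gene list")
    matched = set()
    for gid in pathway_genes:
        if gid not in patterns.index or patterns[gid] != metabolite_trend:
            continue
        if gid not in summary.index:
            continue
        row = summary.loc[gid]
        if row["has_dar"] or row["has_dmr"] or row["has_switch"]:
            matched.add(gid)
    return matched


def build_correlation_network(
    expr: SeasonalExpression,
    tf_ids: Sequence[str],
    target_ids: Sequence[str],
    *,
    r_thresh: float = 0.8,
    over: str = "samples",
) -> pd.DataFrame:
    """Pearson TF-target edges on log2-CPM; keep edges with |r| > r_thresh.

    ``over='samples'`` correlates across all replicate samples (default);
    ``over='means'`` across the three season means. TFs or targets with
    zero variance are skipped with a warning.
    """
    lc = expr.log2_cpm() if over == "samples" else expr.season_means()
    n = lc.shape[1]
    if n < 3:
        raise InsufficientDataError("need >= 3 shared samples for correlation")
    rows = []
    for tf in tf_ids:
        if tf not in lc.index:
            continue
        x = lc.loc[tf].values.astype(float)
        if np.std(x) == 0:
            warnings.warn(f"TF {tf} has zero expression variance; skipped", stacklevel=2)
            continue
        for target in target_ids:
            if target == tf or target not in lc.index:
                continue
            y = lc.loc[target].values.astype(float)
            if np.std(y) == 0:
                continue
            r = float(np.corrcoef(x, y)[0, 1])
            if abs(r) > r_thresh:
                rows.append((tf, target, r, n))
    return pd.DataFrame(rows, columns=["tf_id", "target_id", "r", "n_samples"])


def apply_contrast_filters(
    tf_ids: Sequence[str],
    de_results: Mapping[str, pd.DataFrame] | None,
    dars: Mapping[str, pd.DataFrame] | None,
    dmrs: Mapping[str, Sequence[DMR]] | None,
    gene_compartments: pd.DataFrame | None,
    genes: Sequence[GeneModel],
    *,
    promoter_upstream: int = 3000,
    promoter_downstream: int = 3000,
    peaks: Sequence[Peak] | None = None,
) -> pd.DataFrame:
    """Four summer-contrast evidence flags per TF.

    * ``expr_contrast``: DEG down in SPS->SUS and DEG up in SUS->AUS.
    * ``atac_contrast``: promoter DAR loss in SPS->SUS and gain in SUS->AUS.
    * ``meth_contrast``: promoter DMR hyper in SPS->SUS and hypo in
      SUS->AUS (methylation peaking in summer), any context.
    * ``compartment_A_stable``: label A in all three seasons (NaN fails).

    A layer passed as None yields missing (pd.NA) flags rather than False.
    When ``peaks`` is given, TFs without any promoter-overlapping consensus
    peak get an explanatory note alongside a False accessibility flag.
    """
    gene_map = {g.gene_id: g for g in genes}
    keys = [_comparison_key(a, b) for a, b in COMPARISONS]
    promoters = {
        gid: promoter_interval(
            gene_map[gid].tss, gene_map[gid].strand, gene_map[gid].chrom,
            promoter_upstream, promoter_downstream,
        )
        for gid in tf_ids
        if gid in gene_map
    }

    dar_idx = {}
    if dars is not None:
        for key in keys:
            df = dars[key][dars[key]["is_dar"]].reset_index(drop=True)
            dar_idx[key] = (df, IntervalIndex(_dar_intervals(df, only_called=False)) if len(df) else None)
    dmr_idx = {}
    if dmrs is not None:
        for key in keys:
            ds = list(dmrs[key])
            dmr_idx[key] = (ds, IntervalIndex([d.interval for d in ds]) if ds else None)
    peak_index = IntervalIndex([p.interval for p in peaks]) if peaks else None

    rows = []
    for tf in tf_ids:
        if tf not in promoters:
            raise ValidationError(f"TF {tf!r} missing from annotation")
        promoter = promoters[tf]
        note = ""

        if de_results is None:
            expr_flag = pd.NA
        else:
            de1, de2 = de_results[keys[0]], de_results[keys[1]]
            down1 = tf in de1.index and bool(
                de1.loc[tf, "is_deg"] and de1.loc[tf, "log2fc"] < 0
            )
            up2 = tf in de2.index and bool(
                de2.loc[tf, "is_deg"] and de2.loc[tf, "log2fc"] > 0
            )
            expr_flag = down1 and up2

        if dars is None:
            atac_flag = pd.NA
        else:
            directions = []
            for key in keys:
                df, index = dar_idx[key]
                hits = index.overlapping(promoter) if index else []
                directions.append(set(df.iloc[hits]["direction"]))
            atac_flag = ("loss" in directions[0]) and ("gain" in directions[1])
            if peak_index is not None and not peak_index.overlapping(promoter):
                atac_flag = False
                note = "no promoter peak"

        if dmrs is None:
            meth_flag = pd.NA
        else:
            dirs = []
            for key in keys:
                ds, index = dmr_idx[key]
                hits = index.overlapping(promoter) if index else []
                dirs.append({ds[i].direction for i in hits})
            meth_flag = ("hyper" in dirs[0]) and ("hypo" in dirs[1])

        if gene_compartments is None:
            comp_flag = pd.NA
        elif tf not in gene_compartments.index:
            comp_flag = False
            note = (note + "; " if note else "") + "no compartment call"
        else:
            labels = gene_compartments.loc[tf, list(SEASONS)].tolist()
            if "NaN" in labels:
                comp_flag = False
                note = (note + "; " if note else "") + "missing compartment bin"
            else:
                comp_flag = all(x == "A" for x in labels)

        rows.append((tf, expr_flag, atac_flag, meth_flag, comp_flag, note))

    return pd.DataFrame(
        rows,
        columns=[
            "tf_id",
            "expr_contrast",
            "atac_contrast",
            "meth_contrast",
            "compartment_A_stable",
            "note",
        ],
    ).set_index("tf_id")


FLAG_COLUMNS = ("expr_contrast", "atac_contrast", "meth_contrast", "compartment_A_stable")


@dataclass
class CandidateReport:
    """Ranked TF candidates with the binary four-layer indicator matrix."""

    table: pd.DataFrame  # indexed by tf_id, sorted by rank
    layer_counts: dict[str, int]

    @property
    def top_candidate(self) -> str | None:
        return None if self.table.empty else self.table.index[0]


def intersect_and_rank(edges: pd.DataFrame, flags: pd.DataFrame) -> CandidateReport:
    """Rank network TFs by layers passed, then max |r|, then tf_id.

    Only TFs with >= 1 correlation edge enter the report. Missing flags
    count as not passed but stay distinguishable in the indicator matrix.
    Per-layer counts are reported alongside; the all-layer intersection can
    never exceed any of them.
    """
    if edges.empty:
        warnings.warn("empty correlation edge list; empty candidate report", stacklevel=2)
        return CandidateReport(
            pd.DataFrame(
                columns=[*FLAG_COLUMNS, "n_layers_passed", "max_abs_r", "rank", "note"]
            ),
            {c: 0 for c in FLAG_COLUMNS},
        )
    max_r = edges.groupby("tf_id")["r"].apply(lambda s: float(np.max(np.abs(s))))
    tfs = [t for t in flags.index if t in max_r.index]
    table = flags.loc[tfs, list(FLAG_COLUMNS) + ["note"]].copy()
    booleans = table[list(FLAG_COLUMNS)].fillna(False).astype(bool)
    table["n_layers_passed"] = booleans.sum(axis=1)
    table["max_abs_r"] = max_r.loc[tfs]
    table.index.name = "tf_id"
    table = (
        table.reset_index()
        .sort_values(
            by=["n_layers_passed", "max_abs_r", "tf_id"],
            ascending=[False, False, True],
            kind="stable",
        )
        .set_index("tf_id")
    )
    table["rank"] = np.arange(1, len(table) + 1)
    layer_counts = {c: int(booleans[c].sum()) for c in FLAG_COLUMNS}
    return CandidateReport(table, layer_counts)


def global_layer_correlations(
    expr_lfc: pd.Series,
    accessibility_lfc: pd.Series,
    methylation_delta: pd.Series,
) -> dict[str, dict[str, float]]:
    """Spearman correlation of per-gene fold changes between layers.

    Returns rho, a two-sided p, and a Fisher-z 95% CI for the
    expression-accessibility and expression-methylation pairings, computed
    on the gene universe shared by all three inputs (>= 10 genes).
    """
    common = expr_lfc.index.intersection(accessibility_lfc.index).intersection(
        methylation_delta.index
    )
    if len(common) < 10:
        raise InsufficientDataError(f"only {len(common)} matched genes (< 10)")
    out = {}
    for name, other in (
        ("expression_accessibility", accessibility_lfc),
        ("expression_methylation", methylation_delta),
    ):
        rho, p = stats.spearmanr(expr_lfc.loc[common], other.loc[common])
        z = np.arctanh(np.clip(rho, -0.999999, 0.999999))
        se = 1.0 / np.sqrt(len(common) - 3)
        out[name] = {
            "rho": float(rho),
            "p": float(p),
            "ci_low": float(np.tanh(z - 1.959964 * se)),
            "ci_high": float(np.tanh(z + 1.959964 * se)),
            "n": int(len(common)),
        }
    return out


# ---------------------------------------------------------------------------
# end-to-end screen over a synthetic dataset


def pool_methylation(tables: Sequence[MethylationSiteTable]) -> MethylationSiteTable:
    """Sum counts across replicates sharing an identical site frame."""
    first = tables[0].sites
    meth = first["meth"].to_numpy().copy()
    total = first["total"].to_numpy().copy()
    for t in tables[1:]:
        if len(t) != len(first) or not t.sites["pos"].equals(first["pos"]):
            raise ValidationError("replicate site tables do not align")
        meth += t.sites["meth"].to_numpy()
        total += t.sites["total"].to_numpy()
    pooled = first.copy()
    pooled["meth"] = meth
    pooled["total"] = total
    return MethylationSiteTable(pooled, sample="pooled")


def promoter_methylation_levels(
    methylation: Mapping[str, MethylationSiteTable],
    samples: pd.DataFrame,
    genes: Sequence[GeneModel],
    flank: int = 500,
) -> pd.DataFrame:
    """Per-gene pooled promoter methylation level per season (all contexts)."""
    by_season = {
        s: pool_methylation(
            [methylation[name] for name in samples.index[samples["season"] == s]]
        )
        for s in SEASONS
    }
    rows = {}
    for season, table in by_season.items():
        sites = table.sites
        col = {}
        for chrom, grp in sites.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            meth = grp["meth"].to_numpy()
            total = grp["total"].to_numpy()
            cm = np.concatenate([[0], np.cumsum(meth)])
            ct = np.concatenate([[0], np.cumsum(total)])
            for g in genes:
                if g.chrom != chrom:
                    continue
                lo, hi = np.searchsorted(pos, (g.tss - flank, g.tss + flank + 1))
                t = ct[hi] - ct[lo]
                col[g.gene_id] = (cm[hi] - cm[lo]) / t if t > 0 else np.nan
        rows[season] = col
    return pd.DataFrame(rows)


def run_regulator_screen(ds, cfg: ConfigBundle | None = None) -> dict:
    """Full inference chain on a synthetic dataset.

    Returns a dict with DE tables, DAR tables, DMR lists, compartment
    tracks, gene compartments, the correlation network, the four-layer
    flags, the ranked candidate report, and the global layer correlations.
    """
    from .hic import (
        assign_gene_compartments,
        balance_matrix,
        call_compartments,
        observed_over_expected,
    )
    from .transcriptomics import normalize_expression

    if cfg is None:
        cfg = ConfigBundle()
    expr = normalize_expression(ds.counts, ds.gene_lengths, ds.rna_samples)
    keys = [_comparison_key(a, b) for a, b in COMPARISONS]

    de = {
        _comparison_key(a, b): differential_expression(
            expr, a, b,
            fdr_thresh=cfg.de_fdr, lfc_thresh=cfg.de_lfc,
            min_count=cfg.de_min_count, pseudocount=cfg.cpm_pseudocount,
        )
        for a, b in COMPARISONS
    }
    dars = {
        _comparison_key(a, b): call_dars(
            ds.peaks, ds.peak_counts, ds.atac_samples, a, b,
            lfc_thresh=cfg.dar_lfc, p_thresh=cfg.dar_p,
        )
        for a, b in COMPARISONS
    }

    by_season = {
        s: pool_methylation(
            [ds.methylation[n] for n in ds.rna_samples.index[ds.rna_samples["season"] == s]]
        )
        for s in SEASONS
    }
    chrom_lengths = {c: ds.config.chrom_length for c in ds.config.chrom_names()}
    dmrs: dict[str, list[DMR]] = {}
    for a, b in COMPARISONS:
        found: list[DMR] = []
        for context in ("CG", "CHG", "CHH"):
            found.extend(
                call_dmrs(
                    by_season[a], by_season[b], context,
                    window=cfg.dmr_window, step=cfg.dmr_step,
                    min_sites=cfg.dmr_min_sites, delta=cfg.dmr_delta(context),
                    q_thresh=cfg.dmr_q, min_coverage=cfg.dmr_min_coverage,
                    min_windows=cfg.dmr_min_windows,
                    chrom_lengths=chrom_lengths,
                )
            )
        dmrs[_comparison_key(a, b)] = found

    tracks: dict[str, dict] = {s: {} for s in SEASONS}
    for season in SEASONS:
        for chrom, reps in ds.hic[season].items():
            summed = reps[0].matrix.copy()
            for r in reps[1:]:
                summed = summed + r.matrix
            from .hic import ContactMatrix

            cm = ContactMatrix(chrom, ds.config.bin_size, summed)
            balanced = balance_matrix(
                cm, tol=cfg.hic_balance_tol, max_iter=cfg.hic_balance_max_iter,
                mask_fraction=cfg.hic_mask_fraction,
            )
            oe = observed_over_expected(balanced)
            tracks[season][chrom] = call_compartments(oe, ds.gene_density[chrom])
    gene_compartments = assign_gene_compartments(tracks, ds.genes)

    tf_ids = sorted(g.gene_id for g in ds.genes if g.is_tf)
    targets = ds.manifest.pathway_genes
    edges = build_correlation_network(
        expr, tf_ids, targets, r_thresh=cfg.corr_threshold, over=cfg.corr_over
    )
    network_tfs = sorted(set(edges["tf_id"]))
    flags = apply_contrast_filters(
        network_tfs, de, dars, dmrs, gene_compartments, ds.genes,
        promoter_upstream=cfg.promoter_upstream,
        promoter_downstream=cfg.promoter_downstream,
        peaks=ds.peaks,
    )
    report = intersect_and_rank(edges, flags)

    # layer fold changes for the global correlation summary (SPS -> SUS)
    means = expr.season_means()
    expr_lfc = means["SUS"] - means["SPS"]
    from .transcriptomics import median_of_ratios_size_factors

    lib = ds.peak_counts.sum(axis=0)
    eff = median_of_ratios_size_factors(ds.peak_counts) * float(
        np.exp(np.log(lib).mean())
    )
    lcpm = np.log2(1e6 * (ds.peak_counts + 0.5).div(eff, axis=1))
    atac_means = lcpm.T.groupby(ds.atac_samples["season"]).mean().T
    promoter_peak = {
        g.gene_id: f"peak_{g.gene_id}"
        for g in ds.genes
        if f"peak_{g.gene_id}" in lcpm.index
    }
    atac_lfc = pd.Series(
        {
            gid: atac_means.loc[pk, "SUS"] - atac_means.loc[pk, "SPS"]
            for gid, pk in promoter_peak.items()
        }
    )
    prom_meth = promoter_methylation_levels(
        ds.methylation, ds.rna_samples, ds.genes, flank=cfg.meth_promoter_flank
    )
    meth_delta = (prom_meth["SUS"] - prom_meth["SPS"]).dropna()
    layer_corr = global_layer_correlations(expr_lfc, atac_lfc, meth_delta)

    patterns = classify_seasonal_pattern(expr, deadband=cfg.pattern_deadband)
    deg_union = set().union(*(set(d.index[d["is_deg"]]) for d in de.values()))
    if deg_union:
        summary, fractions = deg_epigenome_classification(
            deg_union, list(dars.values()),
            [d for lst in dmrs.values() for d in lst],
            gene_compartments, ds.genes,
            promoter_upstream=cfg.promoter_upstream,
            promoter_downstream=cfg.promoter_downstream,
        )
        trend_matched = trend_match_structural_genes(targets, patterns, summary)
    else:  # pragma: no cover - default configs always yield DEGs
        summary, fractions, trend_matched = pd.DataFrame(), {}, set()

    return {
        "expr": expr,
        "de": de,
        "dars": dars,
        "dmrs": dmrs,
        "tracks": tracks,
        "gene_compartments": gene_compartments,
        "edges": edges,
        "flags": flags,
        "report": report,
        "layer_correlations": layer_corr,
        "patterns": patterns,
        "deg_summary": summary,
        "deg_fractions": fractions,
        "trend_matched": trend_matched,
    }
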