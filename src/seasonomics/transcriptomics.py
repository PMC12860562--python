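"""Expression normalization, seasonal differential expression, pattern labels,
and hierarchical profile clustering.

The design is 3 seasons (SPS, SUS, AUS) x replicates. Counts are normalized
to FPKM (10^9 * count / (library_size * length)) and log2-CPM with a
pseudocount; per-gene differential testing is a Welch t-test on log2-CPM with
Benjamini-Hochberg correction over all tested genes, thresholded at
FDR < 0.05 and |log2FC| > 1 (both strict, both configurable).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from statsmodels.stats.multitest import multipletests

from .config import SEASONS
from .exceptions import (
    DegenerateDataError,
    InsufficientDataError,
    ValidationError,
)

PATTERNS = (
    "high-low-high",
    "low-high-low",
    "monotone-up",
    "monotone-down",
    "flat",
    "other",
)


class SeasonalExpression:
    """Gene x sample counts over the seasonal replicate design.

    Parameters
    ----------
    counts
        Nonnegative integer DataFrame, genes x samples.
    samples
        DataFrame indexed by sample name with columns ``season`` and
        ``replicate``; its index must match the count columns.
    lengths
        Per-gene transcript lengths in bp (for FPKM).
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        samples: pd.DataFrame,
        lengths: pd.Series,
    ):
        if set(counts.columns) != set(samples.index):
            raise ValidationError("count columns and sample table disagree")
        if (counts.values < 0).any():
            raise ValidationError("negative counts")
        missing = set(counts.index) - set(lengths.index)
        if missing:
            raise ValidationError(f"genes without length: {sorted(missing)[:5]} ...")
        lib = counts.sum(axis=0)
        if (lib <= 0).any():
            raise ValidationError("zero library size in at least one sample")
        if (lengths.loc[counts.index] <= 0).any():
            raise ValidationError("non-positive gene length")
        self.counts = counts
        self.samples = samples.loc[counts.columns]
        self.lengths = lengths.loc[counts.index].astype(float)

    @cached_property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @cached_property
    def size_factors(self) -> pd.Series:
        """Median-of-ratios size factors (geometric mean normalized to 1).

        Robust to a handful of strongly regulated high-abundance genes that
        would otherwise shift every other gene's CPM compositionally.
        """
        return median_of_ratios_size_factors(self.counts)

    @cached_property
    def fpkm(self) -> pd.DataFrame:
        lib = self.library_sizes.values[None, :]
        length = self.lengths.values[:, None]
        return pd.DataFrame(
            1e9 * self.counts.values / (lib * length),
            index=self.counts.index,
            columns=self.counts.columns,
        )

    def log2_cpm(self, pseudocount: float = 0.5) -> pd.DataFrame:
        """log2 counts-per-million on size-factor-corrected libraries."""
        geo_lib = float(np.exp(np.log(self.library_sizes.values).mean()))
        eff = self.size_factors.values[None, :] * geo_lib
        cpm = 1e6 * (self.counts.values + pseudocount) / eff
        return pd.DataFrame(
            np.log2(cpm), index=self.counts.index, columns=self.counts.columns
        )

    def samples_for(self, season: str) -> list[str]:
        sel = self.samples.index[self.samples["season"] == season]
        return list(sel)

    def season_means(self, pseudocount: float = 0.5) -> pd.DataFrame:
        """Per-season mean log2-CPM over replicates (genes x seasons)."""
        lc = self.log2_cpm(pseudocount)
        cols = {}
        for season in SEASONS:
            reps = self.samples_for(season)
            if reps:
                cols[season] = lc[reps].mean(axis=1)
        return pd.DataFrame(cols)

    def season_zscores(self, pseudocount: float = 0.5) -> pd.DataFrame:
        """Row Z-scores of the season-mean vectors (0 where variance is 0)."""
        m = self.season_means(pseudocount)
        mu = m.mean(axis=1)
        sd = m.std(axis=1, ddof=0)
        z = m.sub(mu, axis=0).div(sd.replace(0, np.nan), axis=0)
        return z.fillna(0.0)


def median_of_ratios_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Per-sample median ratio to the geometric-mean reference gene.

    Computed over features observed in every sample; factors are rescaled
    to geometric mean 1. Falls back to relative library size when no
    feature is shared.
    """
    x = counts.values.astype(float)
    shared = (x > 0).all(axis=1)
    if shared.sum() >= 1:
        logx = np.log(x[shared])
        ref = logx.mean(axis=1, keepdims=True)
        sf = np.exp(np.median(logx - ref, axis=0))
    else:
        lib = x.sum(axis=0)
        sf = lib / np.exp(np.log(lib).mean())
    sf = sf / np.exp(np.log(sf).mean())
    return pd.Series(sf, index=counts.columns, name="size_factor")


def normalize_expression(
    counts: pd.DataFrame, lengths: pd.Series, samples: pd.DataFrame
) -> SeasonalExpression:
    """Validate and wrap a raw count matrix into a SeasonalExpression."""
    return SeasonalExpression(counts, samples, lengths)


def _welch_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise Welch t-test p-values; identical constant rows give p = 1."""
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    # both groups constant: nan t-statistic; no evidence either way
    p[np.isnan(p)] = 1.0
    return p


def differential_expression(
    expr: SeasonalExpression,
    season_a: str,
    season_b: str,
    *,
    fdr_thresh: float = 0.05,
    lfc_thresh: float = 1.0,
    min_count: int = 10,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-gene Welch test on log2-CPM between two seasons.

    log2FC is the mean log2-CPM difference (``season_b`` minus ``season_a``).
    Genes whose total raw count over the two groups is below ``min_count``
    are excluded from testing and from the BH correction. A gene is a DEG
    iff ``fdr < fdr_thresh`` and ``|log2fc| > lfc_thresh`` (strict).
    """
    cols_a = expr.samples_for(season_a)
    cols_b = expr.samples_for(season_b)
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise InsufficientDataError(
            f"need >= 2 replicates per season, got {len(cols_a)} and {len(cols_b)}"
        )
    keep = expr.counts[cols_a + cols_b].sum(axis=1) >= min_count
    lc = expr.log2_cpm(pseudocount).loc[keep]
    a = lc[cols_a].values
    b = lc[cols_b].values
    log2fc = b.mean(axis=1) - a.mean(axis=1)
    p = _welch_rows(a, b)
    fdr = multipletests(p, method="fdr_bh")[1] if len(p) else np.array([])
    out = pd.DataFrame(
        {
            "gene_id": lc.index,
            "comparison": f"{season_a}_vs_{season_b}",
            "log2fc": log2fc,
            "p": p,
            "fdr": fdr,
        }
    ).set_index("gene_id")
    out["is_deg"] = (out["fdr"] < fdr_thresh) & (out["log2fc"].abs() > lfc_thresh)
    return out


def classify_pattern_from_means(
    means: np.ndarray | pd.Series, deadband: float = 0.5
) -> str:
    """Label a (SPS, SUS, AUS) log-scale mean vector by its sign pattern.

    Differences below ``deadband`` (log2 units) count as no change.
    high-low-high requires SUS below both SPS and AUS by more than the
    deadband; the symmetric rule gives low-high-low.
    """
    m = np.asarray(means, dtype=float)
    if m.shape != (3,):
        raise ValidationError("need exactly three season means")
    d1, d2 = m[1] - m[0], m[2] - m[1]
    s1 = 0 if abs(d1) <= deadband else (1 if d1 > 0 else -1)
    s2 = 0 if abs(d2) <= deadband else (1 if d2 > 0 else -1)
    if s1 == -1 and s2 == 1:
        return "high-low-high"
    if s1 == 1 and s2 == -1:
        return "low-high-low"
    if s1 >= 0 and s2 >= 0 and (s1, s2) != (0, 0):
        return "monotone-up"
    if s1 <= 0 and s2 <= 0 and (s1, s2) != (0, 0):
        return "monotone-down"
    if (s1, s2) == (0, 0):
        return "flat"
    return "other"


def classify_seasonal_pattern(
    expr: SeasonalExpression,
    gene_id: str | None = None,
    *,
    deadband: float = 0.5,
    pseudocount: float = 0.5,
):
    """Seasonal pattern label(s) from per-season mean log2-CPM.

    With ``gene_id`` returns a single label; otherwise a Series over all
    genes. Invariant under multiplying all counts by a constant (log2-CPM
    differences are compositional).
    """
    means = expr.season_means(pseudocount)
    if gene_id is not None:
        if gene_id not in means.index:
            raise KeyError(f"unknown gene {gene_id!r}")
        return classify_pattern_from_means(means.loc[gene_id, list(SEASONS)], deadband)
    return pd.Series(
        [
            classify_pattern_from_means(row, deadband)
            for row in means[list(SEASONS)].values
        ],
        index=means.index,
        name="pattern",
    )


@dataclass
class ClusterAssignment:
    """Gene -> cluster ids plus a per-cluster pattern label."""

    assignments: pd.Series  # gene_id -> cluster id (1..k)
    cluster_patterns: dict[int, str]
    centroids: pd.DataFrame  # cluster x season (Z-scored means)


def cluster_profiles(
    expr: SeasonalExpression,
    genes: list[str] | None = None,
    k: int = 6,
    *,
    deadband: float = 0.5,
) -> ClusterAssignment:
    """Hierarchical clustering of Z-scored season-mean profiles.

    Ward linkage on Euclidean distance, tree cut at ``k`` clusters. Genes
    are processed in sorted gene_id order so the cut is deterministic.
    Each cluster is labelled by the seasonal pattern of its centroid.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    z = expr.season_zscores()
    if genes is not None:
        z = z.loc[genes]
    z = z.sort_index()
    profiles = z[list(SEASONS)]
    n_distinct = profiles.round(9).drop_duplicates().shape[0]
    if n_distinct < k:
        raise DegenerateDataError(
            f"only {n_distinct} distinct profiles for k={k} clusters"
        )
    if k == 1:
        labels = np.ones(len(profiles), dtype=int)
    else:
        link = linkage(profiles.values, method="ward")
        labels = fcluster(link, t=k, criterion="maxclust")
    assignments = pd.Series(labels, index=profiles.index, name="cluster")
    centroids = profiles.groupby(assignments).mean()
    # centroid deadband scaled down: profiles are Z-scores, not log2 units
    patterns = {
        int(c): classify_pattern_from_means(row, deadband=min(deadband, 0.25))
        for c, row in centroids.iterrows()
    }
    return ClusterAssignment(assignments, patterns, centroids)
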