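"""Synthetic multi-omics dataset with planted ground truth.

Emulates a three-season (SPS spring, SUS summer, AUS autumn) leaf study with
three biological replicates per assay (two for Hi-C): RNA counts, ATAC
consensus peaks with a peak x sample count matrix, per-cytosine methylation
tables in CG/CHG/CHH contexts, binned Hi-C contact matrices, and a targeted
metabolome with external calibration standards.

Planted truth (recorded in a TruthManifest):

* three anthocyanin structural genes (CHS-, F3'H- and ANS-like) with a
  high-low-high expression trend, reduced summer promoter accessibility, and
  (for the F3'H-like gene) summer promoter CG hypermethylation;
* a master MYB-like regulator carrying the full four-layer signature —
  high-low-high expression, a promoter peak losing accessibility in summer,
  summer CG/CHG promoter hypermethylation, and residence in an A-compartment
  bin in all three seasons;
* a WRKY-like positive regulator (expression contrast only) and an ERF-like
  negative regulator (low-high-low expression);
* compartment switch bins (A2A2B and B2A2B) in the Hi-C block structure;
* 15 contrasting metabolites (7 cyanidins including a C3G-like pigment whose
  spring/summer and autumn/summer ratios default to 300x, 5 delphinidins,
  2 pelargonidins, 1 peonidin) within an 87-compound, eight-class panel.

Background genes carry a small cross-layer coupled seasonal modulation
(log2 sd ``expr_mod_sd``) that stays below every calling threshold but gives
the genome-wide expression/accessibility/methylation fold-change couplings
their expected signs. All randomness flows from one seed; a fixed seed gives
byte-identical output files.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .config import CONTEXTS, SEASONS
from .exceptions import ValidationError
from .intervals import GenomicInterval
from .io_formats import (
    GeneModel,
    MethylationSiteTable,
    Peak,
    write_annotation,
    write_contacts,
    write_count_matrix,
    write_methylation,
    write_peaks,
)

TF_FAMILIES = ("MYB", "WRKY", "ERF", "bHLH", "NAC")

# eight-class panel with the published class sizes (total 87)
METABOLITE_CLASS_SIZES = {
    "cyanidins": 24,
    "delphinidins": 23,
    "peonidins": 11,
    "malvidins": 8,
    "petunidins": 7,
    "pelargonidins": 6,
    "proanthocyanidins": 6,
    "flavonoids": 2,
}
# contrasting set: depleted spring->summer, restored summer->autumn
CONTRASTING_BREAKDOWN = {
    "cyanidins": 7,
    "delphinidins": 5,
    "pelargonidins": 2,
    "peonidins": 1,
}

RESERVED = {
    "master_tf": "tfMYB001",
    "positive_tf": "tfWRKY001",
    "negative_tf": "tfERF001",
    "chs": "geneCHS01",
    "f3ph": "geneF3pH01",
    "ans": "geneANS01",
}


@dataclass
class SimulationConfig:
    """Study-design parameters of the synthetic dataset."""

    seed: int = 0
    n_chrom: int = 2
    chrom_length: int = 1_000_000
    n_genes: int = 300
    n_tfs: int = 30
    gene_length: int = 1_500
    bin_size: int = 50_000
    chunk_bins: int = 5  # compartment block width, in bins

    # replicate design: 3 per season for RNA/ATAC/WGBS, 2 per season for Hi-C
    n_rep_rna: int = 3
    n_rep_atac: int = 3
    n_rep_wgbs: int = 3
    n_rep_hic: int = 2

    # planted effect sizes
    expr_fold: float = 8.0
    atac_fold: float = 4.0
    meth_delta: float = 0.3
    metab_fold: float = 300.0  # C3G-like spring/summer ratio
    contrast_metab_fold: float = 20.0  # other contrasting metabolites
    n_switch_aab: int = 3
    n_switch_bab: int = 2

    # background / noise model
    dispersion: float = 0.01
    expr_mod_sd: float = 0.1  # coupled background seasonal modulation, log2
    responsive_fraction: float = 0.3  # genes with strong seasonal programs
    responsive_sd: float = 1.0  # their per-season log2 effect scale
    coupling_atac: float = 0.8
    coupling_meth: float = -0.08
    expr_base_median: float = 800.0
    atac_base_median: float = 200.0
    wgbs_coverage: float = 20.0
    wgbs_precision: float = 100.0  # beta precision (pseudo reads)
    meth_base: tuple = (0.60, 0.35, 0.08)  # CG, CHG, CHH baselines
    meth_season_shift: tuple = (0.0, 0.02, 0.04)  # SPS < SUS < AUS
    meth_spacing: tuple = (15, 20, 10)  # mean bp between sites per context
    summit_dip_amplitude: float = 0.5
    summit_dip_sigma: float = 300.0
    hic_within: float = 200.0
    hic_between: float = 40.0
    metab_cv: float = 0.10
    extraction_volume_ul: float = 500.0
    sample_mass_g: float = 0.05
    promoter_flank: int = 500  # span of planted promoter marks around TSS

    def __post_init__(self) -> None:
        if min(self.n_rep_rna, self.n_rep_atac, self.n_rep_wgbs, self.n_rep_hic) < 1:
            raise ValidationError("replicate counts must be positive")
        if self.n_genes <= 0 or self.n_tfs < 3 or self.n_tfs > self.n_genes:
            raise ValidationError("need 3 <= n_tfs <= n_genes and n_genes > 0")
        if self.chrom_length % self.bin_size != 0:
            raise ValidationError("chrom_length must be a multiple of bin_size")

    @property
    def n_bins(self) -> int:
        return self.chrom_length // self.bin_size

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chrom)]

    def rna_samples(self) -> pd.DataFrame:
        return _sample_table(self.n_rep_rna)

    def atac_samples(self) -> pd.DataFrame:
        return _sample_table(self.n_rep_atac)


def _sample_table(n_rep: int) -> pd.DataFrame:
    rows = [
        (f"{season}_{r + 1}", season, r + 1)
        for season in SEASONS
        for r in range(n_rep)
    ]
    return pd.DataFrame(rows, columns=["sample", "season", "replicate"]).set_index(
        "sample"
    )


@dataclass
class TruthManifest:
    """Planted ground truth, emitted alongside the data."""

    master_tf: str
    positive_tf: str
    negative_tf: str
    structural_genes: list[str]
    pattern: pd.Series  # gene_id -> true seasonal pattern label
    planted_dars: list[GenomicInterval]  # promoter regions losing access in SUS
    planted_dmrs: list[tuple[GenomicInterval, str]]  # SUS-hypermethylated
    bin_labels: dict  # chrom -> season -> list of "A"/"B"
    switch_bins: dict  # chrom -> {bin index: transition string}
    contrasting_metabolites: list[str]
    c3g_id: str
    gene_bins: pd.DataFrame  # gene_id -> chrom, bin

    @property
    def pathway_genes(self) -> list[str]:
        return list(self.structural_genes)

    def true_gene_compartments(self, gene_id: str) -> list[str]:
        row = self.gene_bins.loc[gene_id]
        return [self.bin_labels[row["chrom"]][s][row["bin"]] for s in SEASONS]

    def validate_against(self, genes: list[GeneModel]) -> None:
        ids = {g.gene_id for g in genes}
        planted = {self.master_tf, self.positive_tf, self.negative_tf}
        planted |= set(self.structural_genes)
        missing = planted - ids
        if missing:
            raise ValidationError(f"planted ids missing from annotation: {missing}")

    def to_frame(self) -> pd.DataFrame:
        rows = [("master_tf", self.master_tf),
                ("positive_tf", self.positive_tf),
                ("negative_tf", self.negative_tf),
                ("structural_genes", ",".join(self.structural_genes)),
                ("c3g_id", self.c3g_id),
                ("contrasting_metabolites", ",".join(self.contrasting_metabolites))]
        for iv in self.planted_dars:
            rows.append(("planted_dar", f"{iv.chrom}:{iv.start}-{iv.end}"))
        for iv, ctx in self.planted_dmrs:
            rows.append(("planted_dmr", f"{iv.chrom}:{iv.start}-{iv.end}:{ctx}"))
        for chrom, bins in self.switch_bins.items():
            for b, label in bins.items():
                rows.append(("switch_bin", f"{chrom}:{b}:{label}"))
        for gene, pat in self.pattern.items():
            rows.append(("pattern", f"{gene}:{pat}"))
        return pd.DataFrame(rows, columns=["key", "value"])


@dataclass
class SyntheticDataset:
    """All layers of one simulated study, plus the truth manifest."""

    config: SimulationConfig
    genes: list[GeneModel]
    manifest: TruthManifest
    # RNA
    counts: pd.DataFrame
    rna_samples: pd.DataFrame
    gene_lengths: pd.Series
    # ATAC
    peaks: list[Peak]
    peak_counts: pd.DataFrame
    atac_samples: pd.DataFrame
    # WGBS: sample -> site table
    methylation: dict
    # Hi-C: season -> chrom -> list of replicate matrices
    hic: dict
    gene_density: dict  # chrom -> per-bin TSS count
    # metabolome
    metabolites: pd.DataFrame
    metab_samples: pd.DataFrame
    standards: pd.DataFrame
    responses: pd.DataFrame

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_annotation(self.genes, out / "annotation.gff3")
        write_count_matrix(self.counts, out / "expression_counts.tsv")
        self.rna_samples.to_csv(out / "samples.tsv", sep="\t")
        self.gene_lengths.rename("length").to_csv(out / "gene_lengths.tsv", sep="\t")
        write_peaks(self.peaks, out / "consensus_peaks.narrowPeak")
        write_count_matrix(self.peak_counts, out / "peak_counts.tsv")
        meth_dir = out / "methylation"
        meth_dir.mkdir(exist_ok=True)
        for sample, table in self.methylation.items():
            write_methylation(table, meth_dir / f"{sample}.tsv")
        hic_dir = out / "hic"
        hic_dir.mkdir(exist_ok=True)
        for season, per_chrom in self.hic.items():
            for chrom, reps in per_chrom.items():
                for r, cm in enumerate(reps, start=1):
                    write_contacts(cm, hic_dir / f"{season}_{chrom}_rep{r}.coo.tsv")
        self.metabolites.to_csv(out / "metabolites.tsv", sep="\t", index=False)
        self.standards.to_csv(out / "calibration_standards.tsv", sep="\t", index=False)
        self.responses.to_csv(out / "metabolite_responses.tsv", sep="\t", index=False)
        self.manifest.to_frame().to_csv(out / "truth_manifest.tsv", sep="\t", index=False)
        (out / "simulation_config.yaml").write_text(
            yaml.safe_dump(dataclasses.asdict(self.config), sort_keys=True)
        )


# ---------------------------------------------------------------------------
# genome & compartment scaffold


def _baseline_blocks(cfg: SimulationConfig) -> np.ndarray:
    """Alternating A/B chunks of ``chunk_bins`` bins, starting with A."""
    labels = np.empty(cfg.n_bins, dtype="<U1")
    for b in range(cfg.n_bins):
        labels[b] = "A" if (b // cfg.chunk_bins) % 2 == 0 else "B"
    return labels


def simulate_genome(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[list[GeneModel], TruthManifest]:
    """Place non-overlapping genes, flag TFs, and plant the reserved genes.

    Gene density is ~2.5x higher in baseline-A bins so that the compartment
    eigenvector can be oriented by gene density. The six reserved genes live
    in the first (stable A) chunk of chr1; switch bins are drawn elsewhere.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    chroms = cfg.chrom_names()
    baseline = _baseline_blocks(cfg)

    # seasonal bin labels + switch bins
    bin_labels = {
        c: {s: baseline.copy() for s in SEASONS} for c in chroms
    }
    a_candidates = [
        (c, b)
        for c in chroms
        for b in np.flatnonzero(baseline == "A")
        if not (c == chroms[0] and b < cfg.chunk_bins)  # keep reserved chunk stable
    ]
    b_candidates = [(c, b) for c in chroms for b in np.flatnonzero(baseline == "B")]
    if cfg.n_switch_aab > len(a_candidates) or cfg.n_switch_bab > len(b_candidates):
        raise ValidationError("more switch bins requested than available")
    aab = [a_candidates[i] for i in rng.choice(len(a_candidates), cfg.n_switch_aab, replace=False)]
    bab = [b_candidates[i] for i in rng.choice(len(b_candidates), cfg.n_switch_bab, replace=False)]
    switch_bins: dict[str, dict[int, str]] = {c: {} for c in chroms}
    for c, b in aab:
        bin_labels[c]["AUS"][b] = "B"
        switch_bins[c][int(b)] = "A2A2B"
    for c, b in bab:
        bin_labels[c]["SUS"][b] = "A"
        switch_bins[c][int(b)] = "B2A2B"

    # per-bin gene allocation: heavier in baseline-A bins
    per_chrom = [cfg.n_genes // cfg.n_chrom] * cfg.n_chrom
    per_chrom[0] += cfg.n_genes % cfg.n_chrom
    weights = np.where(baseline == "A", 2.5, 1.0)
    placements: list[tuple[str, int, int, str]] = []  # chrom, start, bin, strand
    for ci, chrom in enumerate(chroms):
        quota = per_chrom[ci] * weights / weights.sum()
        counts = np.floor(quota).astype(int)
        remainder = per_chrom[ci] - counts.sum()
        order = np.argsort(-(quota - counts), kind="stable")
        counts[order[:remainder]] += 1
        for b in range(cfg.n_bins):
            k = counts[b]
            if k == 0:
                continue
            gap = cfg.bin_size // (k + 1)
            if gap <= cfg.gene_length:
                raise ValidationError(
                    "n_genes too large to place without overlap at this bin size"
                )
            for j in range(k):
                start = b * cfg.bin_size + gap * (j + 1) - cfg.gene_length // 2
                start = max(0, min(start, cfg.chrom_length - cfg.gene_length))
                placements.append((chrom, start, b, "+" if (len(placements) % 2 == 0) else "-"))

    placements.sort(key=lambda t: (t[0], t[1]))
    gene_ids = [f"g{i:04d}" for i in range(len(placements))]

    # reserved genes: deterministic slots in the stable-A first chunk of chr1
    reserved_bins = {
        RESERVED["chs"]: 0,
        RESERVED["positive_tf"]: 1,
        RESERVED["master_tf"]: 2,
        RESERVED["f3ph"]: 2,
        RESERVED["negative_tf"]: 3,
        RESERVED["ans"]: 4,
    }
    used: set[int] = set()
    rename: dict[int, str] = {}

    def _pick_slot(preferred_bin: int) -> int:
        for i, p in enumerate(placements):
            if i not in used and p[0] == chroms[0] and p[2] == preferred_bin:
                return i
        for i, p in enumerate(placements):  # anywhere in the stable-A chunk
            if i not in used and p[0] == chroms[0] and p[2] < cfg.chunk_bins:
                return i
        for i in range(len(placements)):
            if i not in used:
                return i
        raise ValidationError("too few genes to place the reserved set")

    for rid, b in reserved_bins.items():
        idx = _pick_slot(b)
        used.add(idx)
        rename[idx] = rid
    for idx, rid in rename.items():
        gene_ids[idx] = rid

    families = {
        RESERVED["master_tf"]: "MYB",
        RESERVED["positive_tf"]: "WRKY",
        RESERVED["negative_tf"]: "ERF",
    }
    # background TFs: away from reserved genes to keep their promoters clean
    eligible = [
        i
        for i, p in enumerate(placements)
        if i not in used
        and all(abs(p[1] - placements[j][1]) > 5_000 or p[0] != placements[j][0] for j in used)
    ]
    n_bg = cfg.n_tfs - 3
    if n_bg > len(eligible):
        raise ValidationError("too few background genes to flag as TFs")
    if n_bg > 0:
        bg_tfs = sorted(rng.choice(eligible, size=n_bg, replace=False))
        for k, i in enumerate(bg_tfs):
            families[gene_ids[i]] = TF_FAMILIES[k % len(TF_FAMILIES)]

    genes = [
        GeneModel(
            gene_ids[i],
            GenomicInterval(p[0], p[1], p[1] + cfg.gene_length, p[3]),
            families.get(gene_ids[i]),
        )
        for i, p in enumerate(placements)
    ]
    gene_bins = pd.DataFrame(
        {"chrom": [p[0] for p in placements], "bin": [p[2] for p in placements]},
        index=pd.Index(gene_ids, name="gene_id"),
    )

    manifest = TruthManifest(
        master_tf=RESERVED["master_tf"],
        positive_tf=RESERVED["positive_tf"],
        negative_tf=RESERVED["negative_tf"],
        structural_genes=[RESERVED["chs"], RESERVED["f3ph"], RESERVED["ans"]],
        pattern=pd.Series(dtype=object),  # filled by simulate_multiomics
        planted_dars=[],
        planted_dmrs=[],
        bin_labels={c: {s: list(bin_labels[c][s]) for s in SEASONS} for c in chroms},
        switch_bins=switch_bins,
        contrasting_metabolites=[],
        c3g_id="",
        gene_bins=gene_bins,
    )
    manifest.validate_against(genes)
    return genes, manifest


# ---------------------------------------------------------------------------
# count model


def _nb_counts(
    rng: np.random.Generator,
    mean: np.ndarray,
    dispersion: float,
    depth: float = 1.0,
) -> np.ndarray:
    """Negative-binomial counts as a Poisson-gamma mixture."""
    if dispersion <= 0:
        lam = mean * depth
    else:
        shape = 1.0 / dispersion
        lam = rng.gamma(shape, mean * dispersion) * depth
    return rng.poisson(lam)


def _promoter_span(g: GeneModel, flank: int, chrom_length: int) -> GenomicInterval:
    lo = max(0, g.tss - flank)
    hi = min(chrom_length, g.tss + flank + 1)
    return GenomicInterval(g.chrom, lo, hi)


# ---------------------------------------------------------------------------
# multi-omics layers


def simulate_multiomics(
    cfg: SimulationConfig,
    genes: list[GeneModel],
    manifest: TruthManifest,
    rng: np.random.Generator,
) -> dict:
    """Expression, accessibility, methylation and Hi-C layers with truth."""
    manifest.validate_against(genes)
    n_genes = len(genes)
    gene_ids = [g.gene_id for g in genes]
    gid_index = {g: i for i, g in enumerate(gene_ids)}
    log2_fold = np.log2(cfg.expr_fold)

    # --- latent seasonal structure -------------------------------------
    # every gene gets a small coupled seasonal modulation; a realistic
    # fraction additionally carries a strong seasonal program (real leaves
    # remodel thousands of genes between seasons, and the multiple-testing
    # behaviour of the screens depends on that signal mass)
    e_mod = rng.normal(0.0, cfg.expr_mod_sd, size=(n_genes, 3))
    n_resp = int(cfg.responsive_fraction * n_genes)
    if n_resp > 0:
        resp = rng.choice(n_genes, size=n_resp, replace=False)
        e_mod[resp] = rng.normal(0.0, cfg.responsive_sd, size=(n_resp, 3))
    planted_effect = np.zeros((n_genes, 3))
    hlh_ids = manifest.structural_genes + [manifest.master_tf, manifest.positive_tf]
    for gid in hlh_ids:
        e_mod[gid_index[gid]] = 0.0
        planted_effect[gid_index[gid]] = (0.0, -log2_fold, 0.0)
    e_mod[gid_index[manifest.negative_tf]] = 0.0
    planted_effect[gid_index[manifest.negative_tf]] = (0.0, log2_fold, 0.0)
    season_log2 = e_mod + planted_effect

    # --- expression ------------------------------------------------------
    base = rng.lognormal(np.log(cfg.expr_base_median), 1.0, size=n_genes)
    planted_base = {
        manifest.structural_genes[0]: 2000.0,
        manifest.structural_genes[1]: 2000.0,
        manifest.structural_genes[2]: 2000.0,
        manifest.master_tf: 1500.0,
        manifest.positive_tf: 1200.0,
        manifest.negative_tf: 1000.0,
    }
    for gid, v in planted_base.items():
        base[gid_index[gid]] = v
    mu = base[:, None] * np.power(2.0, season_log2)  # genes x seasons
    rna_samples = _sample_table(cfg.n_rep_rna)
    depth = rng.uniform(0.7, 1.3, size=len(rna_samples))
    count_cols = {}
    for k, (sample, row) in enumerate(rna_samples.iterrows()):
        s = SEASONS.index(row["season"])
        count_cols[sample] = _nb_counts(rng, mu[:, s], cfg.dispersion, depth[k])
    counts = pd.DataFrame(count_cols, index=pd.Index(gene_ids, name="gene_id"))
    gene_lengths = pd.Series(
        cfg.gene_length, index=pd.Index(gene_ids, name="gene_id"), name="length"
    )
    manifest.pattern = pd.Series(
        {
            gid: _pattern_from_log2(season_log2[i])
            for i, gid in enumerate(gene_ids)
        },
        name="pattern",
    )

    # --- ATAC: consensus peaks + counts ---------------------------------
    peaks: list[Peak] = []
    peak_effect_rows: list[np.ndarray] = []
    half = 200
    for g in genes:
        start = max(0, g.tss - half)
        end = min(cfg.chrom_length, g.tss + half)
        peaks.append(
            Peak(
                GenomicInterval(g.chrom, start, end),
                name=f"peak_{g.gene_id}",
                summit_offset=g.tss - start,
            )
        )
        i = gid_index[g.gene_id]
        eff = cfg.coupling_atac * e_mod[i]
        if g.gene_id in (manifest.master_tf, *manifest.structural_genes):
            eff = np.array([0.0, -np.log2(cfg.atac_fold), 0.0])
        peak_effect_rows.append(eff)
    n_distal = n_genes // 3
    chroms = cfg.chrom_names()
    for j in range(n_distal):
        chrom = chroms[j % cfg.n_chrom]
        start = int(rng.integers(0, cfg.chrom_length - 400))
        peaks.append(
            Peak(GenomicInterval(chrom, start, start + 400), name=f"peak_distal{j:03d}",
                 summit_offset=200)
        )
        peak_effect_rows.append(rng.normal(0.0, 0.05, size=3))
    peak_effects = np.vstack(peak_effect_rows)
    atac_base = rng.lognormal(np.log(cfg.atac_base_median), 0.8, size=len(peaks))
    atac_base[gid_index[manifest.master_tf]] = 400.0
    atac_mu = atac_base[:, None] * np.power(2.0, peak_effects)
    atac_samples = _sample_table(cfg.n_rep_atac)
    atac_depth = rng.uniform(0.7, 1.3, size=len(atac_samples))
    atac_cols = {}
    for k, (sample, row) in enumerate(atac_samples.iterrows()):
        s = SEASONS.index(row["season"])
        atac_cols[sample] = _nb_counts(rng, atac_mu[:, s], cfg.dispersion, atac_depth[k])
    peak_counts = pd.DataFrame(
        atac_cols, index=pd.Index([p.name for p in peaks], name="peak")
    )
    for gid in (manifest.master_tf, *manifest.structural_genes):
        g = genes[gid_index[gid]]
        manifest.planted_dars.append(
            _promoter_span(g, cfg.promoter_flank, cfg.chrom_length)
        )

    # --- WGBS -------------------------------------------------------------
    methylation = _simulate_methylation(cfg, genes, manifest, e_mod, peaks, rng)

    # --- Hi-C -------------------------------------------------------------
    from .hic import ContactMatrix  # deferred to keep module load cheap

    hic: dict[str, dict[str, list]] = {}
    idx = np.arange(cfg.n_bins)
    decay = 1.0 / (1.0 + np.abs(idx[:, None] - idx[None, :]))
    for season in SEASONS:
        hic[season] = {}
        for chrom in chroms:
            labels = np.asarray(manifest.bin_labels[chrom][season])
            same = labels[:, None] == labels[None, :]
            mean = np.where(same, cfg.hic_within, cfg.hic_between) * decay
            reps = []
            for _ in range(cfg.n_rep_hic):
                upper = rng.poisson(mean)
                sym = np.triu(upper) + np.triu(upper, 1).T
                reps.append(ContactMatrix(chrom, cfg.bin_size, sym.astype(float)))
            hic[season][chrom] = reps
    gene_density = {
        chrom: np.bincount(
            [g.tss // cfg.bin_size for g in genes if g.chrom == chrom],
            minlength=cfg.n_bins,
        ).astype(float)
        for chrom in chroms
    }

    return {
        "counts": counts,
        "rna_samples": rna_samples,
        "gene_lengths": gene_lengths,
        "peaks": peaks,
        "peak_counts": peak_counts,
        "atac_samples": atac_samples,
        "methylation": methylation,
        "hic": hic,
        "gene_density": gene_density,
    }


def _pattern_from_log2(season_log2: np.ndarray, deadband: float = 0.5) -> str:
    from .transcriptomics import classify_pattern_from_means

    return classify_pattern_from_means(season_log2, deadband)


def _simulate_methylation(
    cfg: SimulationConfig,
    genes: list[GeneModel],
    manifest: TruthManifest,
    e_mod: np.ndarray,
    peaks: list[Peak],
    rng: np.random.Generator,
) -> dict[str, MethylationSiteTable]:
    """Beta-binomial per-cytosine tables for all nine WGBS samples."""
    chroms = cfg.chrom_names()
    gid_index = {g.gene_id: i for i, g in enumerate(genes)}
    summits = {
        chrom: np.sort(
            np.array([p.summit for p in peaks if p.chrom == chrom and p.summit is not None])
        )
        for chrom in chroms
    }
    frames = []
    mus = []  # per-season site means, aligned with frames
    for chrom in chroms:
        pos_list, ctx_list = [], []
        for ctx, spacing in zip(CONTEXTS, cfg.meth_spacing):
            gaps = rng.exponential(spacing, size=int(cfg.chrom_length / spacing * 1.2)) + 1
            pos = np.cumsum(gaps).astype(np.int64)
            pos = pos[pos < cfg.chrom_length]
            pos_list.append(pos)
            ctx_list.append(np.full(len(pos), ctx))
        pos = np.concatenate(pos_list)
        ctx = np.concatenate(ctx_list)
        order = np.argsort(pos, kind="stable")
        pos, ctx = pos[order], ctx[order]
        strand = rng.choice(np.array(["+", "-"]), size=len(pos))
        base_map = dict(zip(CONTEXTS, cfg.meth_base))
        base = np.array([base_map[c] for c in ctx])
        base = np.clip(base + rng.normal(0.0, 0.05, size=len(pos)), 0.02, 0.98)
        # accessibility footprint: methylation dips around peak summits
        s = summits[chrom]
        if len(s):
            nearest = np.searchsorted(s, pos)
            left = s[np.clip(nearest - 1, 0, len(s) - 1)]
            right = s[np.clip(nearest, 0, len(s) - 1)]
            d = np.minimum(np.abs(pos - left), np.abs(pos - right)).astype(float)
            dip = 1.0 - cfg.summit_dip_amplitude * np.exp(
                -(d**2) / (2 * cfg.summit_dip_sigma**2)
            )
            base = base * dip
        mu = base[:, None] + np.asarray(cfg.meth_season_shift)[None, :]
        # coupled promoter modulation + planted summer hypermethylation
        for g in genes:
            if g.chrom != chrom:
                continue
            span = _promoter_span(g, cfg.promoter_flank, cfg.chrom_length)
            lo, hi = np.searchsorted(pos, (span.start, span.end))
            if hi <= lo:
                continue
            mu[lo:hi] += cfg.coupling_meth * e_mod[gid_index[g.gene_id]][None, :]
            if g.gene_id == manifest.master_tf:
                sel = np.isin(ctx[lo:hi], ("CG", "CHG"))
                mu[lo:hi][sel, 1] += cfg.meth_delta
            elif g.gene_id == manifest.structural_genes[1]:  # F3'H-like
                sel = ctx[lo:hi] == "CG"
                mu[lo:hi][sel, 1] += cfg.meth_delta
        mu = np.clip(mu, 0.01, 0.99)
        frames.append(
            pd.DataFrame({"chrom": chrom, "pos": pos, "strand": strand, "context": ctx})
        )
        mus.append(mu)
    sites = pd.concat(frames, ignore_index=True)
    mu_all = np.vstack(mus)

    for gid in (manifest.master_tf,):
        g = genes[gid_index[gid]]
        span = _promoter_span(g, cfg.promoter_flank, cfg.chrom_length)
        manifest.planted_dmrs.extend([(span, "CG"), (span, "CHG")])
    g = genes[gid_index[manifest.structural_genes[1]]]
    manifest.planted_dmrs.append(
        (_promoter_span(g, cfg.promoter_flank, cfg.chrom_length), "CG")
    )

    nu = cfg.wgbs_precision
    tables: dict[str, MethylationSiteTable] = {}
    for season_idx, season in enumerate(SEASONS):
        mu_s = mu_all[:, season_idx]
        alpha, beta = mu_s * nu, (1.0 - mu_s) * nu
        for r in range(cfg.n_rep_wgbs):
            p = rng.beta(alpha, beta)
            total = rng.poisson(cfg.wgbs_coverage, size=len(p))
            meth = rng.binomial(total, p)
            df = sites.copy()
            df["meth"] = meth
            df["total"] = total
            tables[f"{season}_{r + 1}"] = MethylationSiteTable(df, sample=f"{season}_{r + 1}")
    return tables


# ---------------------------------------------------------------------------
# metabolome


def simulate_metabolome(
    cfg: SimulationConfig,
    manifest: TruthManifest,
    rng: np.random.Generator,
    n_rep: int = 3,
) -> dict:
    """87-compound targeted panel with calibration standards and responses.

    Contrasting metabolites follow the anthocyanin high-low-high trend; the
    C3G-like pigment's spring/summer ratio is ``metab_fold`` (default 300).
    """
    if sum(METABOLITE_CLASS_SIZES.values()) != 87:
        raise ValidationError("class sizes must sum to the panel total")
    samples = _sample_table(n_rep)
    names, classes = [], []
    for cls, size in METABOLITE_CLASS_SIZES.items():
        stem = cls[:-1] if cls.endswith("s") else cls
        for i in range(size):
            names.append(f"{stem}_{i + 1:02d}")
            classes.append(cls)
    c3g_id = "cyanidin_3_O_glucoside_like"
    names[0] = c3g_id

    contrasting: list[str] = []
    for cls, k in CONTRASTING_BREAKDOWN.items():
        stem = cls[:-1]
        members = [n for n, c in zip(names, classes) if c == cls][:k]
        contrasting.extend(members)
    manifest.contrasting_metabolites = contrasting
    manifest.c3g_id = c3g_id

    base = rng.lognormal(np.log(5.0), 1.0, size=len(names))
    low_mask = np.isin(classes, ["malvidins", "petunidins"])
    base[low_mask] = rng.lognormal(np.log(0.2), 0.5, size=low_mask.sum())
    base[names.index(c3g_id)] = 60.0

    mean = np.tile(base[:, None], (1, 3))  # metabolite x season
    for m in contrasting:
        i = names.index(m)
        fold = cfg.metab_fold if m == c3g_id else cfg.contrast_metab_fold
        mean[i, 1] = base[i] / fold
    content_cols = {}
    for sample, row in samples.iterrows():
        s = SEASONS.index(row["season"])
        noise = rng.normal(0.0, cfg.metab_cv, size=len(names))
        content_cols[sample] = mean[:, s] * np.exp(noise)
    table = pd.DataFrame(content_cols)
    table.insert(0, "metabolite", names)
    table.insert(1, "class", classes)

    # external calibration: 14 levels from 0.01 to 5000 ng/ml per analyte
    levels = np.geomspace(0.01, 5000.0, 14)
    slopes = rng.uniform(500.0, 2000.0, size=len(names))
    intercepts = rng.uniform(0.0, 50.0, size=len(names))
    # constant (homoscedastic) detector noise: keeps the unweighted OLS
    # calibration well behaved at the low end of the 0.01-5000 ng/ml range
    std_rows = []
    for i, name in enumerate(names):
        resp = slopes[i] * levels + intercepts[i] + rng.normal(0.0, 2.0, size=len(levels))
        for lvl, r in zip(levels, resp):
            std_rows.append((name, lvl, r))
    standards = pd.DataFrame(std_rows, columns=["metabolite", "concentration", "response"])

    # instrument responses back-computed through the content formula
    factor = 100_000 * cfg.sample_mass_g / cfg.extraction_volume_ul  # content -> ng/ml
    resp_cols = {}
    for sample in samples.index:
        c = table[sample].values * factor
        resp_cols[sample] = slopes * c + intercepts + rng.normal(0.0, 0.5, size=len(names))
    responses = pd.DataFrame(resp_cols)
    responses.insert(0, "metabolite", names)
    responses.insert(1, "class", classes)

    return {
        "metabolites": table,
        "metab_samples": samples,
        "standards": standards,
        "responses": responses,
    }


# ---------------------------------------------------------------------------
# orchestration


def simulate(cfg: SimulationConfig | None = None) -> SyntheticDataset:
    """Generate the full dataset from one seed (deterministic)."""
    if cfg is None:
        cfg = SimulationConfig()
    rng = np.random.default_rng(cfg.seed)
    genes, manifest = simulate_genome(cfg, rng)
    omics = simulate_multiomics(cfg, genes, manifest, rng)
    metab = simulate_metabolome(cfg, manifest, rng, n_rep=cfg.n_rep_rna)
    return SyntheticDataset(config=cfg, genes=genes, manifest=manifest, **omics, **metab)


# ---------------------------------------------------------------------------
# focused benchmark generators


def simulate_null_counts(
    n_features: int,
    n_a: int = 3,
    n_b: int = 3,
    mean: float = 200.0,
    dispersion: float = 0.05,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Count matrix with no group effect (type-I error benchmarks)."""
    rng = np.random.default_rng(seed)
    mu = rng.lognormal(np.log(mean), 1.0, size=n_features)
    cols = {}
    samples = []
    for grp, n in (("A", n_a), ("B", n_b)):
        for r in range(n):
            name = f"{grp}_{r + 1}"
            cols[name] = _nb_counts(rng, mu, dispersion)
            samples.append((name, grp, r + 1))
    counts = pd.DataFrame(cols, index=pd.Index([f"f{i:05d}" for i in range(n_features)]))
    sample_df = pd.DataFrame(samples, columns=["sample", "season", "replicate"]).set_index("sample")
    return counts, sample_df


def simulate_null_metabolites(
    n_metabolites: int,
    n_a: int = 3,
    n_b: int = 3,
    cv: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Metabolite table with no group effect."""
    rng = np.random.default_rng(seed)
    base = rng.lognormal(np.log(5.0), 1.0, size=n_metabolites)
    classes = [
        list(METABOLITE_CLASS_SIZES)[i % len(METABOLITE_CLASS_SIZES)]
        for i in range(n_metabolites)
    ]
    cols = {}
    for grp, n in (("A", n_a), ("B", n_b)):
        for r in range(n):
            cols[f"{grp}_{r + 1}"] = base * np.exp(rng.normal(0.0, cv, size=n_metabolites))
    table = pd.DataFrame(cols)
    table.insert(0, "metabolite", [f"m{i:04d}" for i in range(n_metabolites)])
    table.insert(1, "class", classes)
    return table


def simulate_dmr_benchmark(
    seed: int = 0,
    n_regions: int = 20,
    region_length: int = 300,
    chrom_length: int = 200_000,
    level_in: tuple[float, float] = (0.8, 0.2),
    level_background: float = 0.3,
    coverage: float = 30.0,
    spacing: int = 12,
    precision: float | None = None,
) -> tuple[MethylationSiteTable, MethylationSiteTable, list[GenomicInterval]]:
    """Two CG samples with planted differential regions for recovery scoring.

    Counts are binomial around the regional mean (the standard DMR-caller
    benchmark model, isolating window/merge logic under sampling noise);
    pass a beta ``precision`` to add site-level overdispersion, under which
    the pooled count test is expectedly anti-conservative.
    """
    rng = np.random.default_rng(seed)
    gaps = rng.exponential(spacing, size=int(chrom_length / spacing * 1.2)) + 1
    pos = np.cumsum(gaps).astype(np.int64)
    pos = pos[pos < chrom_length]
    starts = np.linspace(0, chrom_length - region_length, n_regions + 2)[1:-1].astype(int)
    truth = [GenomicInterval("chr1", int(s), int(s + region_length)) for s in starts]
    mu_a = np.full(len(pos), level_background)
    mu_b = np.full(len(pos), level_background)
    for iv in truth:
        sel = (pos >= iv.start) & (pos < iv.end)
        mu_a[sel] = level_in[0]
        mu_b[sel] = level_in[1]
    tables = []
    for mu in (mu_a, mu_b):
        if precision is None:
            p = mu
        else:
            p = rng.beta(mu * precision, (1 - mu) * precision)
        total = rng.poisson(coverage, size=len(pos))
        meth = rng.binomial(total, p)
        df = pd.DataFrame(
            {
                "chrom": "chr1",
                "pos": pos,
                "strand": "+",
                "context": "CG",
                "meth": meth,
                "total": total,
            }
        )
        tables.append(MethylationSiteTable(df))
    return tables[0], tables[1], truth
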