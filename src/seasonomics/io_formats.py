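"""On-disk formats and the coordinate-convention boundary.

GFF3 gene annotations (1-based closed on disk), narrowPeak-style peak files
(0-based half-open), per-cytosine methylation tables (1-based positions on
disk), binned contact matrices (COO triplets or dense TSV), and plain TSV
count matrices. All readers emit objects in the package-internal 0-based
half-open convention; writers invert the conversion exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .config import CONTEXTS
from .exceptions import ParseError, ValidationError
from .intervals import GenomicInterval

GFF_COLUMNS = 9
NARROWPEAK_COLUMNS = 10


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class GeneModel:
    """A gene with its interval and strand-derived TSS.

    TF status is carried as an annotation attribute (``tf_family``), not
    inferred from sequence.
    """

    gene_id: str
    interval: GenomicInterval
    tf_family: str | None = None

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValidationError("gene_id must be non-empty")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def tss(self) -> int:
        """0-based TSS: start on '+', end - 1 on '-'."""
        if self.interval.strand == "-":
            return self.interval.end - 1
        return self.interval.start

    @property
    def is_tf(self) -> bool:
        return self.tf_family is not None


@dataclass(frozen=True)
class Peak:
    """A narrowPeak-style accessible region with score and summit offset."""

    interval: GenomicInterval
    name: str = "."
    score: float = 0.0
    summit_offset: int = -1

    def __post_init__(self) -> None:
        if self.summit_offset >= len(self.interval):
            raise ValidationError(
                f"summit offset {self.summit_offset} outside peak {self.interval}"
            )

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def summit(self) -> int | None:
        """Absolute summit position, or None when no summit was recorded."""
        if self.summit_offset < 0:
            return None
        return self.interval.start + self.summit_offset


class MethylationSiteTable:
    """Per-cytosine methylated/total counts with context labels.

    Backed by a DataFrame with columns chrom, pos (0-based), strand,
    context in {CG, CHG, CHH}, meth, total.
    """

    COLUMNS = ("chrom", "pos", "strand", "context", "meth", "total")

    def __init__(self, sites: pd.DataFrame, sample: str = ""):
        missing = set(self.COLUMNS) - set(sites.columns)
        if missing:
            raise ValidationError(f"methylation table missing columns {sorted(missing)}")
        sites = sites.loc[:, list(self.COLUMNS)].reset_index(drop=True)
        bad_ctx = set(sites["context"].unique()) - set(CONTEXTS)
        if bad_ctx:
            raise ValidationError(f"unknown methylation context(s): {sorted(bad_ctx)}")
        if (sites["meth"] > sites["total"]).any():
            raise ValidationError("methylated count exceeds total coverage")
        if (sites["meth"] < 0).any() or (sites["total"] < 0).any():
            raise ValidationError("negative methylation counts")
        if (sites["pos"] < 0).any():
            raise ValidationError("negative site position")
        self.sites = sites
        self.sample = sample

    def __len__(self) -> int:
        return len(self.sites)

    def for_context(self, context: str) -> pd.DataFrame:
        if context not in CONTEXTS:
            raise ValidationError(f"unknown context {context!r}")
        return self.sites[self.sites["context"] == context]

    def levels(self) -> pd.Series:
        """Per-site methylation level meth/total (NaN where uncovered)."""
        with np.errstate(invalid="ignore", divide="ignore"):
            lv = self.sites["meth"] / self.sites["total"]
        return lv


# ---------------------------------------------------------------------------
# GFF3 gene annotation


def _parse_gff_attributes(text: str) -> dict[str, str]:
    attrs = {}
    for chunk in text.strip().strip(";").split(";"):
        if not chunk:
            continue
        if "=" not in chunk:
            raise ValueError(f"malformed attribute {chunk!r}")
        key, value = chunk.split("=", 1)
        attrs[key.strip()] = value.strip()
    return attrs


def read_annotation(path: str | Path) -> list[GeneModel]:
    """Read gene records from a GFF3-like file into 0-based half-open models."""
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != GFF_COLUMNS:
                raise ParseError(
                    f"{path}:{lineno}: expected {GFF_COLUMNS} tab-separated "
                    f"fields, got {len(fields)}"
                )
            chrom, _source, ftype, start, end, _score, strand, _phase, attr = fields
            if ftype != "gene":
                continue
            try:
                start_i, end_i = int(start), int(end)
                attrs = _parse_gff_attributes(attr)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if "ID" not in attrs:
                raise ParseError(f"{path}:{lineno}: gene record without ID attribute")
            gene_id = attrs["ID"]
            if gene_id in seen:
                raise ValidationError(f"{path}:{lineno}: duplicate gene_id {gene_id!r}")
            seen.add(gene_id)
            try:
                # GFF3 is 1-based closed; internal is 0-based half-open.
                interval = GenomicInterval(chrom, start_i - 1, end_i, strand)
            except ValidationError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            genes.append(GeneModel(gene_id, interval, attrs.get("tf_family")))
    return genes


def write_annotation(genes: Sequence[GeneModel], path: str | Path) -> None:
    lines = ["##gff-version 3"]
    for g in genes:
        attrs = f"ID={g.gene_id}"
        if g.tf_family is not None:
            attrs += f";tf_family={g.tf_family}"
        lines.append(
            "\t".join(
                [
                    g.interval.chrom,
                    "seasonomics",
                    "gene",
                    str(g.interval.start + 1),
                    str(g.interval.end),
                    ".",
                    g.interval.strand,
                    ".",
                    attrs,
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# narrowPeak-style peaks


def read_peaks(path: str | Path) -> list[Peak]:
    """Read BED6+4 narrowPeak records (0-based half-open on disk)."""
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) != NARROWPEAK_COLUMNS:
                raise ParseError(
                    f"{path}:{lineno}: expected {NARROWPEAK_COLUMNS} columns, "
                    f"got {len(fields)}"
                )
            chrom, start, end, name, _score, strand, signal, _p, _q, summit = fields
            try:
                interval = GenomicInterval(chrom, int(start), int(end), strand)
                peak = Peak(interval, name, float(signal), int(summit))
            except (ValueError, ValidationError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            peaks.append(peak)
    return peaks


def write_peaks(peaks: Sequence[Peak], path: str | Path) -> None:
    lines = []
    for p in peaks:
        lines.append(
            "\t".join(
                [
                    p.interval.chrom,
                    str(p.interval.start),
                    str(p.interval.end),
                    p.name,
                    "0",
                    p.interval.strand,
                    repr(p.score),
                    "-1",
                    "-1",
                    str(p.summit_offset),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# per-cytosine methylation tables


def read_methylation(path: str | Path, sample: str = "") -> MethylationSiteTable:
    """Read a tab-separated per-cytosine table (1-based positions on disk)."""
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={
            "chrom": str,
            "pos": np.int64,
            "strand": str,
            "context": str,
            "meth": np.int64,
            "total": np.int64,
        },
    )
    missing = set(MethylationSiteTable.COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    df = df.copy()
    df["pos"] = df["pos"] - 1  # 1-based on disk -> 0-based internal
    return MethylationSiteTable(df, sample=sample or Path(path).stem)


def write_methylation(table: MethylationSiteTable, path: str | Path) -> None:
    out = table.sites.copy()
    out["pos"] = out["pos"] + 1
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# binned contact matrices


def read_contacts(
    path: str | Path,
    bin_size: int,
    chrom_length: int,
    chrom: str = "chr",
    fmt: str = "auto",
):
    """Read a binned intra-chromosomal contact matrix.

    COO triplet text (``bin_i<TAB>bin_j<TAB>count``) or a dense TSV of the
    full matrix. The input is symmetrized by taking the elementwise maximum
    of the two triangles. Returns a :class:`seasonomics.hic.ContactMatrix`
    of dimension ``ceil(chrom_length / bin_size)``.
    """
    from .hic import ContactMatrix  # deferred: keeps hic importable standalone

    n_bins = -(-chrom_length // bin_size)
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            rows.append(line.split("\t"))
    if fmt == "auto":
        if not rows:
            fmt = "coo"
        elif len(rows[0]) == 3 and n_bins != 3:
            fmt = "coo"
        elif len(rows[0]) == n_bins:
            fmt = "dense"
        else:
            fmt = "coo" if len(rows[0]) == 3 else "dense"
    mat = np.zeros((n_bins, n_bins), dtype=float)
    if fmt == "coo":
        for lineno, fields in enumerate(rows, start=1):
            if len(fields) != 3:
                raise ParseError(f"{path}:{lineno}: expected 3 columns")
            i, j, count = int(fields[0]), int(fields[1]), float(fields[2])
            if count < 0:
                raise ValidationError(f"{path}:{lineno}: negative contact count")
            if not (0 <= i < n_bins and 0 <= j < n_bins):
                raise ValidationError(f"{path}:{lineno}: bin index out of range")
            mat[i, j] = max(mat[i, j], count)
    else:
        if len(rows) != n_bins:
            raise ParseError(
                f"{path}: dense matrix has {len(rows)} rows, expected {n_bins}"
            )
        for lineno, fields in enumerate(rows, start=1):
            if len(fields) != n_bins:
                raise ParseError(f"{path}:{lineno}: expected {n_bins} columns")
            vals = np.asarray([float(x) for x in fields])
            if (vals < 0).any():
                raise ValidationError(f"{path}:{lineno}: negative contact count")
            mat[lineno - 1] = vals
    mat = np.maximum(mat, mat.T)
    return ContactMatrix(chrom=chrom, bin_size=bin_size, matrix=mat)


def write_contacts(cm, path: str | Path) -> None:
    """Write the upper triangle (incl. diagonal) of a ContactMatrix as COO."""
    lines = []
    n = cm.matrix.shape[0]
    for i in range(n):
        for j in range(i, n):
            v = cm.matrix[i, j]
            if v != 0:
                lines.append(f"{i}\t{j}\t{v:g}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# plain matrices


def read_count_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df < 0).any().any():
        raise ValidationError(f"{path}: negative counts")
    return df


def write_count_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t")
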