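"""Hi-C contact matrices: balancing, distance normalization, A/B
compartment eigenvector calls, and three-season switch classification.

The compartment call is the classical one: the leading eigenvector of the
Pearson-correlation matrix of the distance-normalized (observed/expected)
balanced map, with its sign oriented so that positive values correlate with
gene density. Bins with positive oriented eigenvector are labelled A
(active, gene dense), negative B, masked bins NaN.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import SEASONS
from .exceptions import (
    ConvergenceError,
    DegenerateDataError,
    ValidationError,
)


@dataclass
class ContactMatrix:
    """Symmetric nonnegative binned intra-chromosomal contact matrix."""

    chrom: str
    bin_size: int
    matrix: np.ndarray
    mask: np.ndarray = field(default=None)  # True = bad/excluded bin

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValidationError("contact matrix must be square")
        if (m < 0).any():
            raise ValidationError("negative contact counts")
        if not np.allclose(m, m.T):
            raise ValidationError("contact matrix must be symmetric")
        self.matrix = m
        if self.mask is None:
            self.mask = np.zeros(m.shape[0], dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != (m.shape[0],):
                raise ValidationError("mask length must match matrix dimension")

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[0]

    def good_bins(self) -> np.ndarray:
        return np.flatnonzero(~self.mask)


def balance_matrix(
    cm: ContactMatrix,
    tol: float = 1e-5,
    max_iter: int = 500,
    mask_fraction: float = 0.02,
) -> ContactMatrix:
    """Iterative proportional fitting to equal marginals (Sinkhorn-Knopp).

    Bins with zero marginal are masked, along with the
    ``floor(mask_fraction * n)`` lowest-marginal bins (a low-coverage
    filter; at toy bin counts this masks nothing). Convergence is reached
    when every unmasked marginal deviates from the common target by less
    than ``tol`` (relative); otherwise a ConvergenceError carries the
    residual. Symmetry is preserved exactly.
    """
    marginals = cm.matrix.sum(axis=1)
    mask = cm.mask | (marginals == 0)
    n_extra = int(mask_fraction * cm.n_bins)
    if n_extra > 0:
        order = np.argsort(marginals)
        candidates = [i for i in order if not mask[i]][:n_extra]
        mask[candidates] = True
    good = np.flatnonzero(~mask)
    if good.size == 0:
        raise DegenerateDataError("all bins masked")
    sub = cm.matrix[np.ix_(good, good)].astype(float)
    if (sub.sum(axis=1) == 0).any():
        # marginal became zero after masking partners
        extra = good[sub.sum(axis=1) == 0]
        mask[extra] = True
        good = np.flatnonzero(~mask)
        sub = cm.matrix[np.ix_(good, good)].astype(float)
    residual = np.inf
    for _ in range(max_iter):
        s = sub.sum(axis=1)
        residual = float(np.abs(s / s.mean() - 1).max())
        if residual < tol:
            break
        scale = np.sqrt(s / s.mean())
        sub = sub / np.outer(scale, scale)
    else:
        raise ConvergenceError(
            f"balancing did not converge in {max_iter} iterations "
            f"(residual {residual:.3g})",
            residual=residual,
        )
    out = np.zeros_like(cm.matrix)
    out[np.ix_(good, good)] = sub
    return ContactMatrix(cm.chrom, cm.bin_size, out, mask=mask)


def observed_over_expected(cm: ContactMatrix) -> ContactMatrix:
    """Divide each entry by the mean of its |i-j| diagonal over unmasked bins.

    Idempotent on unmasked entries; entries on empty or zero-mean diagonals
    are left at zero.
    """
    n = cm.n_bins
    good = ~cm.mask
    pair_good = np.outer(good, good)
    out = np.zeros_like(cm.matrix)
    idx = np.arange(n)
    offsets = np.abs(idx[:, None] - idx[None, :])
    for d in range(n):
        sel = (offsets == d) & pair_good
        if not sel.any():
            continue
        mean = cm.matrix[sel].mean()
        if mean > 0:
            out[sel] = cm.matrix[sel] / mean
    return ContactMatrix(cm.chrom, cm.bin_size, out, mask=cm.mask.copy())


@dataclass
class CompartmentTrack:
    """Per-bin oriented eigenvector values and A/B/NaN labels."""

    chrom: str
    bin_size: int
    values: np.ndarray  # NaN at masked bins
    labels: list[str]  # "A", "B" or "NaN"

    @property
    def n_bins(self) -> int:
        return len(self.labels)

    def to_frame(self) -> pd.DataFrame:
        starts = np.arange(self.n_bins) * self.bin_size
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "start": starts,
                "end": starts + self.bin_size,
                "eigenvector": self.values,
                "label": self.labels,
            }
        )


def call_compartments(
    oe: ContactMatrix, gene_density: np.ndarray
) -> CompartmentTrack:
    """A/B labels from the leading eigenvector of the O/E correlation matrix.

    The eigenvector sign is arbitrary; it is oriented to correlate
    positively with per-bin gene density, so A (> 0) is the gene-dense
    compartment. Labels are invariant to scaling the contact matrix by a
    positive constant.
    """
    gene_density = np.asarray(gene_density, dtype=float)
    if gene_density.shape != (oe.n_bins,):
        raise ValidationError("gene_density length must match bin count")
    good = oe.good_bins()
    if good.size < 4:
        raise DegenerateDataError("need >= 4 unmasked bins")
    sub = oe.matrix[np.ix_(good, good)]
    if np.allclose(sub.std(axis=1), 0):
        raise DegenerateDataError("zero-variance O/E matrix; compartments undefined")
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(sub)
    if np.isnan(corr).any():
        raise DegenerateDataError("degenerate correlation matrix (zero-variance bin)")
    eigvals, eigvecs = np.linalg.eigh(corr)
    vec = eigvecs[:, -1]
    dens = gene_density[good]
    if np.std(dens) > 0 and np.std(vec) > 0:
        orient = np.corrcoef(vec, dens)[0, 1]
        if orient < 0:
            vec = -vec
    values = np.full(oe.n_bins, np.nan)
    values[good] = vec
    labels = [
        "NaN" if np.isnan(v) else ("A" if v > 0 else "B") for v in values
    ]
    return CompartmentTrack(oe.chrom, oe.bin_size, values, labels)


def classify_switches(
    tracks: Mapping[str, CompartmentTrack],
    seasons: Sequence[str] = SEASONS,
) -> tuple[pd.DataFrame, Counter]:
    """Per-bin three-season label strings (e.g. ``A2A2B``) and their counts.

    Bins masked in any season carry ``NaN`` inside their string and are
    tallied separately from the 8 clean patterns.
    """
    track_list = [tracks[s] for s in seasons]
    n = track_list[0].n_bins
    if any(t.n_bins != n or t.bin_size != track_list[0].bin_size for t in track_list):
        raise ValidationError("tracks do not share binning")
    strings = ["2".join(t.labels[i] for t in track_list) for i in range(n)]
    counts = Counter(strings)
    table = pd.DataFrame(
        {
            "chrom": track_list[0].chrom,
            "bin": np.arange(n),
            "switch": strings,
        }
    )
    return table, counts


def assign_gene_compartments(
    tracks: Mapping[str, Mapping[str, CompartmentTrack]],
    genes: Sequence,
    seasons: Sequence[str] = SEASONS,
) -> pd.DataFrame:
    """Gene -> per-season compartment label of the bin containing its TSS.

    ``tracks`` maps season -> chrom -> CompartmentTrack. Genes whose TSS
    falls outside the binned range get NaN with a warning.
    """
    rows = {}
    for g in genes:
        labels = []
        for season in seasons:
            track = tracks[season].get(g.chrom)
            if track is None:
                labels.append("NaN")
                continue
            b = g.tss // track.bin_size
            if not (0 <= b < track.n_bins):
                warnings.warn(f"TSS of {g.gene_id} outside binned range", stacklevel=2)
                labels.append("NaN")
            else:
                labels.append(track.labels[b])
        rows[g.gene_id] = labels
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(seasons))
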