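"""Tunable thresholds for every layer of the screen, with literature defaults.

Defaults follow the conventions quoted throughout the pipeline: differential
expression at FDR < 0.05 (strict) and |log2FC| > 1 (strict); differential
accessibility at |log2FC| >= 0.58 (inclusive) and raw p <= 0.01 (inclusive);
TF-target network edges at |r| > 0.8 (strict).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import yaml

from .exceptions import ValidationError

log = logging.getLogger(__name__)

SEASONS = ("SPS", "SUS", "AUS")
CONTEXTS = ("CG", "CHG", "CHH")


@dataclass
class ConfigBundle:
    """All tunable thresholds of the analysis chain."""

    # differential expression (Welch on log2-CPM + BH)
    de_fdr: float = 0.05
    de_lfc: float = 1.0
    de_min_count: int = 10
    cpm_pseudocount: float = 0.5

    # differential accessibility (DiffBind-style thresholds)
    dar_lfc: float = 0.58
    dar_p: float = 0.01

    # differential metabolite accumulation
    dam_q: float = 0.05
    dam_lfc: float = 1.0
    dam_pseudocount: float = 0.01

    # DMR window caller
    dmr_window: int = 100
    dmr_step: int = 50
    dmr_min_sites: int = 5
    dmr_delta_cg: float = 0.1
    dmr_delta_chg: float = 0.1
    dmr_delta_chh: float = 0.05
    dmr_q: float = 0.05
    dmr_min_coverage: int = 4
    dmr_min_windows: int = 2

    # peak-to-gene annotation
    promoter_upstream: int = 3000
    promoter_downstream: int = 3000
    # promoter span used for per-gene methylation summaries (bp around TSS)
    meth_promoter_flank: int = 500
    meth_mode: str = "promoter"  # or "gene_body"

    # TF correlation network
    corr_threshold: float = 0.8
    corr_over: str = "samples"  # or "means"
    corr_targets_rule: str = "any"  # edge to >=1 structural gene, or "all"

    # Hi-C compartments
    hic_mask_fraction: float = 0.02
    hic_balance_tol: float = 1e-5
    hic_balance_max_iter: int = 500

    # seasonal pattern labelling
    pattern_deadband: float = 0.5

    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("de_fdr", "dar_p", "dam_q", "dmr_q"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValidationError(f"{name} must lie in (0, 1), got {v}")
        if self.promoter_upstream < 0 or self.promoter_downstream < 0:
            raise ValidationError("promoter window sizes must be non-negative")
        if self.dmr_step <= 0 or self.dmr_window <= 0:
            raise ValidationError("DMR window and step must be positive")
        if self.corr_over not in ("samples", "means"):
            raise ValidationError("corr_over must be 'samples' or 'means'")
        if self.meth_mode not in ("promoter", "gene_body"):
            raise ValidationError("meth_mode must be 'promoter' or 'gene_body'")

    def dmr_delta(self, context: str) -> float:
        return {
            "CG": self.dmr_delta_cg,
            "CHG": self.dmr_delta_chg,
            "CHH": self.dmr_delta_chh,
        }[context]

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ConfigBundle":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
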