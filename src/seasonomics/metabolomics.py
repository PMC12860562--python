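"""Targeted metabolomics: calibration-based quantification, class
aggregation, differential accumulation (DAM) calling, and the
contrasting-pattern screen for pigments depleted in summer and restored in
autumn.

Contents are quantified from external calibration curves via
``content (ug/g) = c * V / (100000 * m)`` with ``c`` the curve-derived
concentration (ng/ml), ``V`` the extraction volume (ul) and ``m`` the sample
mass (g).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import (
    DegenerateDataError,
    InsufficientDataError,
    ValidationError,
)

METABOLITE_CLASSES = (
    "cyanidins",
    "delphinidins",
    "peonidins",
    "malvidins",
    "petunidins",
    "pelargonidins",
    "proanthocyanidins",
    "flavonoids",
)


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear external calibration curve for one analyte."""

    analyte: str
    slope: float  # response per (ng/ml)
    intercept: float
    level_range: tuple[float, float]
    r_squared: float

    def concentration(self, response: float | np.ndarray) -> float | np.ndarray:
        """Invert the curve: response -> concentration (ng/ml)."""
        return (np.asarray(response, dtype=float) - self.intercept) / self.slope


def fit_calibration(
    standards: Sequence[tuple[float, float]], analyte: str = ""
) -> CalibrationCurve:
    """Ordinary least squares fit of response on concentration.

    Requires >= 3 standards at >= 2 distinct concentrations; a noiseless
    line is recovered exactly (r^2 = 1).
    """
    if len(standards) < 3:
        raise InsufficientDataError(
            f"need >= 3 calibration standards, got {len(standards)}"
        )
    conc = np.asarray([s[0] for s in standards], dtype=float)
    resp = np.asarray([s[1] for s in standards], dtype=float)
    if np.ptp(conc) == 0:
        raise DegenerateDataError("zero variance in standard concentrations")
    fit = stats.linregress(conc, resp)
    if fit.slope <= 0:
        raise DegenerateDataError(f"non-positive calibration slope {fit.slope:g}")
    return CalibrationCurve(
        analyte=analyte,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        level_range=(float(conc.min()), float(conc.max())),
        r_squared=float(fit.rvalue**2),
    )


def quantify_content(c: float, volume_ul: float, mass_g: float) -> float:
    """Tissue content in ug/g from curve concentration c (ng/ml)."""
    if volume_ul <= 0 or mass_g <= 0:
        raise ValidationError("extraction volume and sample mass must be positive")
    if c < 0:
        raise ValidationError("concentration must be >= 0")
    return c * volume_ul / (100_000 * mass_g)


def validate_metabolite_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the metabolite/class/content layout and the closed vocabulary."""
    for col in ("metabolite", "class"):
        if col not in table.columns:
            raise ValidationError(f"metabolite table missing column {col!r}")
    bad = set(table["class"].unique()) - set(METABOLITE_CLASSES)
    if bad:
        raise ValidationError(f"unknown metabolite class(es): {sorted(bad)}")
    sample_cols = [c for c in table.columns if c not in ("metabolite", "class")]
    if (table[sample_cols].values < 0).any():
        raise ValidationError("negative metabolite content")
    return table


def aggregate_by_class(
    table: pd.DataFrame, samples: pd.DataFrame | None = None
) -> tuple[pd.Series, pd.DataFrame]:
    """Per-class metabolite counts and per-class summed content.

    Returns ``(counts, content)`` where counts sum to the table size and the
    content columns are per-season sums when a sample->season map is given,
    per-sample sums otherwise. Totals are conserved exactly.
    """
    if table.empty:
        raise ValidationError("empty metabolite table")
    validate_metabolite_table(table)
    counts = table.groupby("class")["metabolite"].count()
    sample_cols = [c for c in table.columns if c not in ("metabolite", "class")]
    content = table.groupby("class")[sample_cols].sum()
    if samples is not None:
        content = content.T.groupby(samples.loc[content.columns, "season"]).sum().T
    return counts, content


def call_dams(
    table: pd.DataFrame,
    samples_a: Sequence[str],
    samples_b: Sequence[str],
    *,
    q_thresh: float = 0.05,
    lfc_thresh: float = 1.0,
    pseudocount: float = 0.01,
    comparison: str = "",
) -> pd.DataFrame:
    """Differentially accumulated metabolites between two replicate groups.

    log2FC is computed on group means with a pseudocount (B relative to A);
    significance is a Welch t-test on log2-transformed contents with BH
    correction. A metabolite is a DAM iff ``q < q_thresh`` and
    ``|log2fc| >= lfc_thresh``.
    """
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise InsufficientDataError("need >= 2 replicates per group")
    validate_metabolite_table(table)
    a = table[list(samples_a)].values.astype(float)
    b = table[list(samples_b)].values.astype(float)
    log2fc = np.log2(b.mean(axis=1) + pseudocount) - np.log2(a.mean(axis=1) + pseudocount)
    la, lb = np.log2(a + pseudocount), np.log2(b + pseudocount)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.asarray(stats.ttest_ind(la, lb, axis=1, equal_var=False).pvalue)
    p[np.isnan(p)] = 1.0
    q = multipletests(p, method="fdr_bh")[1]
    out = pd.DataFrame(
        {
            "metabolite": table["metabolite"].values,
            "class": table["class"].values,
            "comparison": comparison,
            "log2fc": log2fc,
            "p": p,
            "q_value": q,
        }
    ).set_index("metabolite")
    out["is_dam"] = (out["q_value"] < q_thresh) & (out["log2fc"].abs() >= lfc_thresh)
    out["direction"] = np.where(out["log2fc"] > 0, "up", "down")
    return out


def contrasting_metabolite_screen(
    dams_sps_sus: pd.DataFrame, dams_sus_aus: pd.DataFrame
) -> tuple[set[str], pd.Series]:
    """Metabolites depleted spring->summer and restored summer->autumn.

    Returns the intersection {down in SPS->SUS} & {up in SUS->AUS} together
    with its per-class breakdown. The result is a subset of both DAM sets.
    """
    down = set(
        dams_sps_sus.index[dams_sps_sus["is_dam"] & (dams_sps_sus["direction"] == "down")]
    )
    up = set(
        dams_sus_aus.index[dams_sus_aus["is_dam"] & (dams_sus_aus["direction"] == "up")]
    )
    selected = down & up
    classes = dams_sps_sus.loc[sorted(selected), "class"]
    breakdown = classes.value_counts().sort_index() if len(selected) else pd.Series(dtype=int)
    return selected, breakdown


def quantify_table(
    responses: pd.DataFrame,
    standards: pd.DataFrame,
    *,
    volume_ul: float,
    mass_g: float,
) -> pd.DataFrame:
    """Quantify a metabolite x sample response matrix via per-analyte curves.

    ``responses`` carries columns ``metabolite``, ``class`` plus one column
    per sample; ``standards`` carries ``metabolite``, ``concentration``,
    ``response``. Contents falling below each curve's lowest standard are
    flagged (column ``below_loq_any``), not censored.
    """
    sample_cols = [c for c in responses.columns if c not in ("metabolite", "class")]
    rows = []
    flags = []
    for _, row in responses.iterrows():
        std = standards[standards["metabolite"] == row["metabolite"]]
        curve = fit_calibration(
            list(zip(std["concentration"], std["response"])), analyte=row["metabolite"]
        )
        conc = np.maximum(curve.concentration(row[sample_cols].values.astype(float)), 0.0)
        content = np.array([quantify_content(c, volume_ul, mass_g) for c in conc])
        rows.append(content)
        flags.append(bool((conc < curve.level_range[0]).any()))
    out = pd.DataFrame(rows, columns=sample_cols)
    out.insert(0, "metabolite", responses["metabolite"].values)
    out.insert(1, "class", responses["class"].values)
    out["below_loq_any"] = flags
    return out
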