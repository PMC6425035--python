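"""Differential-expression summaries and the viability formula.

The DE statistics themselves (fold changes, adjusted p-values) are consumed
as a table produced upstream by a count model; this module classifies genes,
stratifies DE counts by parental-expression decile, and crosses promoter
H3K27me3 categories with DE direction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .domains import CATEGORIES

__all__ = [
    "DEStatRecord",
    "ViabilityMeasurement",
    "classify_de",
    "decile_counts",
    "category_de_crosstab",
    "viability_percent",
    "read_de_table",
]

DE_LABELS = ("Up", "Down", "NS")


@dataclass
class DEStatRecord:
    """One gene's differential-expression statistics (K27M vs non-K27M)."""

    gene: str
    log2fc: float
    padj: Optional[float]
    parental_expression: float
    de_label: str = "NS"


def read_de_table(path) -> pd.DataFrame:
    """TSV with columns gene, log2fc, padj, parental_expression."""
    df = pd.read_csv(path, sep="\t")
    missing = {"gene", "log2fc", "padj", "parental_expression"} - set(df.columns)
    if missing:
        raise ValueError(f"DE table missing columns {sorted(missing)}")
    return df


def classify_de(
    records, lfc_cut: float = 1.0, alpha: float = 0.05
) -> pd.DataFrame:
    """Label genes Up / Down / NS by fold change and adjusted p-value.

    Up: log2fc > lfc_cut and padj < alpha; Down: log2fc < -lfc_cut and
    padj < alpha; otherwise NS. Records with missing padj are skipped with a
    warning and labelled NS.
    """
    df = _as_frame(records)
    missing = df["padj"].isna()
    if missing.any():
        warnings.warn(
            f"{int(missing.sum())} records lack padj and were labelled NS",
            stacklevel=2,
        )
    label = np.array(["NS"] * len(df), dtype=object)
    ok = ~missing
    up = ok & (df["log2fc"] > lfc_cut) & (df["padj"] < alpha)
    down = ok & (df["log2fc"] < -lfc_cut) & (df["padj"] < alpha)
    label[up.to_numpy()] = "Up"
    label[down.to_numpy()] = "Down"
    out = df.copy()
    out["de_label"] = label
    return out


def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records.reset_index(drop=True)
    return pd.DataFrame(
        [
            (r.gene, r.log2fc, r.padj, r.parental_expression)
            for r in records
        ],
        columns=["gene", "log2fc", "padj", "parental_expression"],
    )


def expression_deciles(parental_expression: Sequence[float]) -> np.ndarray:
    """Decile index (0..9) of every gene by parental expression.

    Deciles are defined over *all* genes, lowest expression first; tied
    values share the lower decile (rank method 'min'). Any monotone transform
    of the expression values yields identical deciles.
    """
    expr = np.asarray(parental_expression, dtype=float)
    n = expr.size
    if n < 10:
        raise ValueError("need at least 10 genes to form deciles")
    ranks = rankdata(expr, method="min") - 1  # 0-based, ties -> lowest rank
    return np.minimum((ranks * 10 // n).astype(int), 9)


def decile_counts(records) -> pd.DataFrame:
    """Up/Down DE-gene counts per parental-expression decile (10 x 2 table)."""
    df = _as_frame(records)
    if "de_label" not in df.columns:
        raise ValueError("records must carry de_label; run classify_de first")
    decile = expression_deciles(df["parental_expression"])
    table = pd.DataFrame(
        0, index=pd.RangeIndex(1, 11, name="decile"), columns=["Up", "Down"]
    )
    for direction in ("Up", "Down"):
        counts = np.bincount(decile[df["de_label"] == direction], minlength=10)
        table[direction] = counts
    return table


def category_de_crosstab(
    promoter_categories: Mapping[str, str],
    de_labels: Mapping[str, str],
) -> pd.DataFrame:
    """Cross promoter H3K27me3 categories with DE direction per gene.

    ``promoter_categories`` maps gene -> {Gained, Absent, Lost, Retained};
    genes missing from ``de_labels`` count toward totals as non-DE. Returns
    one row per category with n_up, n_down, n_total and the Up/Down fractions.
    """
    rows = []
    for gene, cat in promoter_categories.items():
        if cat not in CATEGORIES:
            raise ValueError(f"unknown category label {cat!r} for {gene}")
        rows.append((gene, cat, de_labels.get(gene, "NS")))
    df = pd.DataFrame(rows, columns=["gene", "category", "de_label"])
    out = []
    for cat in CATEGORIES:
        sub = df[df["category"] == cat]
        n_total = len(sub)
        n_up = int((sub["de_label"] == "Up").sum())
        n_down = int((sub["de_label"] == "Down").sum())
        out.append(
            {
                "category": cat,
                "n_up": n_up,
                "n_down": n_down,
                "n_total": n_total,
                "frac_up": n_up / n_total if n_total else 0.0,
                "frac_down": n_down / n_total if n_total else 0.0,
            }
        )
    return pd.DataFrame(out).set_index("category")


# ---------------------------------------------------------------------------
# Viability


@dataclass(frozen=True)
class ViabilityMeasurement:
    """Alamar-blue absorbances of a test well and its positive control.

    A1/A2: test-well absorbance at 570/600 nm; P1/P2: control-well absorbance
    at 570/600 nm; O1/O2: molar extinction coefficients of oxidized dye at
    570 nm (80586) and 600 nm (117216).
    """

    A1: float
    A2: float
    P1: float
    P2: float
    O1: float = 80586.0
    O2: float = 117216.0

    def __post_init__(self) -> None:
        if self.P1 <= 0 or self.P2 <= 0:
            raise ValueError("control absorbances must be positive")


def viability_percent(m: ViabilityMeasurement) -> float:
    """Percentage viability of treated relative to control cells:

    100 * (O2*A1 - O1*A2) / (O2*P1 - O1*P2).
    """
    den = m.O2 * m.P1 - m.O1 * m.P2
    if den == 0:
        raise ValueError("degenerate control measurement (zero denominator)")
    return 100.0 * (m.O2 * m.A1 - m.O1 * m.A2) / den
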