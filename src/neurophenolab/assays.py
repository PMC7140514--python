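"""Molecular assay reductions: comparative Ct (ddCt) and ELISA normalisation.

Relative expression uses the comparative method with amplification
efficiency fixed at 2: per sample, dCt = Ct(gene) - Ct(reference gene);
per condition, ddCt = mean dCt(condition) - mean dCt(reference condition);
reported values are -ddCt (higher expression => larger value) and the fold
change 2**(-ddCt). Amyloid-beta ELISA concentrations are normalised by the
culture's protein content; the Ab42/Ab40 ratio is computed on raw
concentrations and is therefore normalisation-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidParameterError, MissingReferenceError

DEFAULT_REFERENCE_GENE = "ActB"


@dataclass
class CtTable:
    """Ct values by (gene, condition, replicate) with named references."""

    table: pd.DataFrame                  # gene, condition, replicate, ct
    reference_gene: str = DEFAULT_REFERENCE_GENE
    reference_condition: str | None = None

    def __post_init__(self) -> None:
        missing = {"gene", "condition", "ct"} - set(self.table.columns)
        if missing:
            raise InvalidParameterError(f"Ct table lacks columns: {sorted(missing)}")
        if not np.isfinite(self.table["ct"]).all():
            raise InvalidParameterError("Ct values must be finite")
        for cond, sub in self.table.groupby("condition"):
            if self.reference_gene not in set(sub["gene"]):
                raise MissingReferenceError(
                    f"reference gene {self.reference_gene!r} missing for "
                    f"condition {cond!r}")


@dataclass
class ExpressionMatrix:
    """-ddCt and fold change by (gene, condition)."""

    neg_ddct: pd.DataFrame               # genes x conditions
    fold: pd.DataFrame
    reference_condition: str

    def to_heatmap_csv(self, path: str) -> None:
        self.neg_ddct.to_csv(path)


def compute_ddct(table: CtTable) -> ExpressionMatrix:
    """Comparative-Ct relative expression against the reference condition."""
    df = table.table
    ref_cond = table.reference_condition
    if ref_cond is None or ref_cond not in set(df["condition"]):
        raise MissingReferenceError(
            f"reference condition {ref_cond!r} not present")
    # dCt per (condition, replicate): gene Ct minus reference-gene Ct
    keys = ["condition"] + (["replicate"] if "replicate" in df.columns else [])
    ref = (df[df["gene"] == table.reference_gene]
           .groupby(keys)["ct"].mean().rename("ref_ct"))
    genes = df[df["gene"] != table.reference_gene]
    merged = genes.join(ref, on=keys)
    merged["dct"] = merged["ct"] - merged["ref_ct"]
    mean_dct = merged.pivot_table(index="gene", columns="condition",
                                  values="dct", aggfunc="mean")
    ddct = mean_dct.sub(mean_dct[ref_cond], axis=0)
    neg = -ddct
    return ExpressionMatrix(neg_ddct=neg, fold=2.0 ** neg,
                            reference_condition=ref_cond)


@dataclass
class ElisaTable:
    """Per-sample amyloid-beta concentrations and culture protein content."""

    table: pd.DataFrame                  # sample, ab40_pg_ml, ab42_pg_ml, protein_ug
    normalized: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        missing = {"ab40_pg_ml", "ab42_pg_ml", "protein_ug"} - set(self.table.columns)
        if missing:
            raise InvalidParameterError(
                f"ELISA table lacks columns: {sorted(missing)}")


def normalize_elisa(table: ElisaTable) -> ElisaTable:
    """Protein-normalise Ab40/Ab42 and compute the Ab42/40 ratio.

    Rows with non-positive protein are flagged invalid (normalised values
    NaN); the ratio uses raw concentrations and needs Ab40 > 0.
    """
    df = table.table.copy()
    valid = df["protein_ug"] > 0
    df["valid"] = valid
    df["ab40_pg_per_ug"] = np.where(valid, df["ab40_pg_ml"] / df["protein_ug"],
                                    np.nan)
    df["ab42_pg_per_ug"] = np.where(valid, df["ab42_pg_ml"] / df["protein_ug"],
                                    np.nan)
    df["ab42_40_ratio"] = np.where(df["ab40_pg_ml"] > 0,
                                   df["ab42_pg_ml"] / df["ab40_pg_ml"], np.nan)
    return ElisaTable(table.table, normalized=df)
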