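"""Relative quantification of qPCR Ct tables by the Livak 2^-ddCt method.

Target Ct values are normalized to a reference gene (default the 5.8S
rRNA) within each condition (dCt), then to a calibrator condition (ddCt);
relative expression is 2^-ddCt.  Replicate dCt values are averaged per
condition before the ddCt step, so the calibrator's mean fold change is 1
by construction; the standard error comes from per-replicate folds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = ["CtTable", "ddct", "expression_series"]

REFERENCE_GENE = "5.8S rRNA"


@dataclass
class CtTable:
    """Rows of (gene, condition, replicate, Ct)."""

    data: pd.DataFrame  # columns: gene, condition, replicate, ct

    REQUIRED = ("gene", "condition", "replicate", "ct")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"Ct table missing columns: {missing}")
        if (self.data["ct"] <= 0).any():
            raise ValueError("Ct values must be positive")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "CtTable":
        return cls(pd.read_csv(path, sep="\t"))

    def genes(self) -> list[str]:
        return sorted(self.data["gene"].unique())

    def conditions(self) -> list[str]:
        return list(dict.fromkeys(self.data["condition"]))


def ddct(
    ct_target_treat: float,
    ct_ref_treat: float,
    ct_target_cal: float,
    ct_ref_cal: float,
) -> float:
    """2^-((Ct_tgt,treat - Ct_ref,treat) - (Ct_tgt,cal - Ct_ref,cal))."""
    for v in (ct_target_treat, ct_ref_treat, ct_target_cal, ct_ref_cal):
        if v is None or math.isnan(v):
            raise ValueError("missing Ct value")
    d_treat = ct_target_treat - ct_ref_treat
    d_cal = ct_target_cal - ct_ref_cal
    return 2.0 ** (-(d_treat - d_cal))


def expression_series(
    table: CtTable,
    gene: str,
    calibrator: str = "0h",
    reference_gene: str = REFERENCE_GENE,
) -> pd.DataFrame:
    """Per-condition relative expression: mean +/- SE over replicates.

    Returns a frame with columns condition, fold, se, n ordered as the
    conditions appear in the table; the calibrator row has fold 1.
    """
    df = table.data
    if gene not in set(df["gene"]):
        raise ValueError(f"gene {gene!r} not in Ct table")
    conditions = table.conditions()
    if calibrator not in conditions:
        raise ValueError(f"calibrator condition {calibrator!r} not in Ct table")

    def dct(cond: str) -> pd.Series:
        tgt = df[(df.gene == gene) & (df.condition == cond)].set_index("replicate")["ct"]
        ref = df[(df.gene == reference_gene) & (df.condition == cond)].set_index(
            "replicate"
        )["ct"]
        if ref.empty:
            raise ValueError(f"reference gene missing for condition {cond!r}")
        if tgt.empty:
            raise ValueError(f"gene {gene!r} missing for condition {cond!r}")
        aligned = tgt - ref.reindex(tgt.index)
        if aligned.isna().any():
            raise ValueError(f"unmatched replicates for condition {cond!r}")
        return aligned

    cal_mean = dct(calibrator).mean()
    rows = []
    for cond in conditions:
        d = dct(cond)
        folds = 2.0 ** (-(d - cal_mean))
        mean_fold = 2.0 ** (-(d.mean() - cal_mean))
        se = float(folds.std(ddof=1) / math.sqrt(len(folds))) if len(folds) > 1 else 0.0
        rows.append({"condition": cond, "fold": float(mean_fold), "se": se, "n": len(d)})
    return pd.DataFrame(rows)
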