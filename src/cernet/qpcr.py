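"""Relative qPCR quantification by the 2^-ddCt method.

Per sample and gene, technical-replicate Ct values are averaged first;
dCt = Ct(target) - Ct(reference gene); ddCt = dCt - mean dCt over the
control-group samples; fold = 2^-ddCt. Because the control baseline is the
arithmetic mean of control dCt, control-group folds have geometric mean
exactly 1. Group comparisons use Welch's two-sample t-test on fold values,
summarized as mean +/- SEM (sd/sqrt(n), ddof=1).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["ddct", "group_compare", "DeltaDeltaCtModel", "QPCRResults"]

CT_COLUMNS = ("sample_id", "group", "gene_id", "replicate", "ct")


def _check_ct(ct: pd.DataFrame) -> None:
    missing = set(CT_COLUMNS) - set(ct.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")


def ddct(ct: pd.DataFrame, reference_gene: str,
         control_group: str) -> pd.DataFrame:
    """Per-sample relative expression (2^-ddCt) for every non-reference gene.

    Returns one row per (sample, gene) with group, delta_ct, delta_delta_ct
    and fold. Raises if the reference gene is missing from any sample or the
    control group is empty.
    """
    _check_ct(ct)
    mean_ct = (ct.groupby(["sample_id", "group", "gene_id"], sort=True)["ct"]
               .mean().reset_index())
    ref = (mean_ct.loc[mean_ct["gene_id"] == reference_gene]
           .set_index("sample_id")["ct"])
    samples = mean_ct["sample_id"].unique()
    missing = [s for s in samples if s not in ref.index]
    if missing:
        raise ValueError(f"reference gene {reference_gene!r} not measured in "
                         f"sample(s): {missing}")
    if not (mean_ct["group"] == control_group).any():
        raise ValueError(f"control group {control_group!r} has no samples")

    tgt = mean_ct.loc[mean_ct["gene_id"] != reference_gene].copy()
    tgt["delta_ct"] = tgt["ct"] - ref.reindex(tgt["sample_id"]).to_numpy()
    baseline = (tgt.loc[tgt["group"] == control_group]
                .groupby("gene_id")["delta_ct"].mean())
    tgt["delta_delta_ct"] = tgt["delta_ct"] - baseline.reindex(tgt["gene_id"]).to_numpy()
    tgt["fold"] = np.exp2(-tgt["delta_delta_ct"])
    return tgt[["sample_id", "group", "gene_id", "delta_ct",
                "delta_delta_ct", "fold"]].reset_index(drop=True)


def group_compare(rel: pd.DataFrame, gene_id: str) -> dict:
    """Mean +/- SEM of fold per group and Welch's t-test p for one gene."""
    sub = rel.loc[rel["gene_id"] == gene_id]
    groups = sorted(sub["group"].unique())
    if len(groups) != 2:
        raise ValueError(f"gene {gene_id!r}: expected 2 groups, got {groups}")
    out = {"gene_id": gene_id}
    vals = {}
    for g in groups:
        x = sub.loc[sub["group"] == g, "fold"].to_numpy()
        if x.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
        vals[g] = x
        out[g] = {"n": int(x.size), "mean": float(x.mean()),
                  "sem": float(x.std(ddof=1) / np.sqrt(x.size))}
    t, p = stats.ttest_ind(vals[groups[0]], vals[groups[1]], equal_var=False)
    out["t"] = float(t)
    out["p_value"] = float(p)
    return out


@dataclass
class QPCRResults:
    relative_expression: pd.DataFrame
    reference_gene: str
    control_group: str

    def compare(self, gene_id: str) -> dict:
        return group_compare(self.relative_expression, gene_id)

    def gene_summary(self) -> pd.DataFrame:
        rows = []
        for gene in sorted(self.relative_expression["gene_id"].unique()):
            c = self.compare(gene)
            groups = [g for g in c if isinstance(c[g], dict)]
            row = {"gene_id": gene, "t": c["t"], "p_value": c["p_value"]}
            for g in groups:
                row[f"mean_{g}"] = c[g]["mean"]
                row[f"sem_{g}"] = c[g]["sem"]
                row[f"n_{g}"] = c[g]["n"]
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [f"2^-ddCt relative expression "
                 f"(reference {self.reference_gene}, "
                 f"control group {self.control_group!r})"]
        for _, row in self.gene_summary().iterrows():
            means = ", ".join(f"{c[5:]}: {row[c]:.3g} +/- {row['sem_' + c[5:]]:.2g}"
                              for c in row.index if c.startswith("mean_"))
            lines.append(f"  {row['gene_id']}: {means}; "
                         f"t = {row['t']:.3g}, p = {row['p_value']:.3g}")
        return "\n".join(lines)

    def to_tsv(self, path: str | Path) -> None:
        self.relative_expression.to_csv(path, sep="\t", index=False,
                                        float_format="%.6g")


class DeltaDeltaCtModel:
    """Model object: Ct table + reference gene + control group."""

    def __init__(self, ct: pd.DataFrame, reference_gene: str,
                 control_group: str = "control") -> None:
        _check_ct(ct)
        self.ct = ct
        self.reference_gene = reference_gene
        self.control_group = control_group

    @classmethod
    def from_tsv(cls, path: str | Path, reference_gene: str,
                 control_group: str = "control") -> "DeltaDeltaCtModel":
        return cls(pd.read_csv(path, sep="\t"), reference_gene, control_group)

    def fit(self) -> QPCRResults:
        rel = ddct(self.ct, self.reference_gene, self.control_group)
        return QPCRResults(rel, self.reference_gene, self.control_group)
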