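"""ceRNA (lncRNA–miRNA–mRNA) network inference.

Candidate ceRNA pairs are lncRNA–mRNA pairs sharing miRNA regulators. A pair
passes when (1) the number of shared miRNAs exceeds ``shared_min`` (default
5, strictly), (2) the upper-tail hypergeometric p-value of the overlap is
below ``p_max`` and its BH-adjusted FDR below ``fdr_max`` (both 0.01 by
default), and (3) the two transcripts are co-expressed: Pearson r >= r_min
(default 0.7) with two-sided p < r_p_max (0.05). Positive correlation is
required because ceRNA partners respond in the same direction to shared
miRNA availability.

The hypergeometric null draws the mRNA's regulator set at random from the
miRNA universe of the interaction table: with M distinct miRNAs, nA of them
targeting the lncRNA and nB the mRNA, the shared count k is tested as
P(X >= k), X ~ Hypergeometric(M, nA, nB).

The differential network keeps a triplet (lncRNA, miRNA, mRNA) only if the
pair passed, the miRNA targets both partners, and all three members are
differentially expressed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust

__all__ = ["CeRNAThresholds", "shared_mirna_count", "hypergeom_pvalue",
           "pair_coexpression", "target_mirna_sets", "call_cerna_pairs",
           "extract_differential_network", "CeRNAModel", "CeRNAResults"]


@dataclass(frozen=True)
class CeRNAThresholds:
    shared_min: int = 5     # shared miRNAs must be strictly greater
    p_max: float = 0.01
    fdr_max: float = 0.01
    r_min: float = 0.7
    r_p_max: float = 0.05


def shared_mirna_count(set_a: Iterable[str], set_b: Iterable[str]) -> int:
    """Number of miRNAs regulating both partners."""
    return len(set(set_a) & set(set_b))


def hypergeom_pvalue(M: int, nA: int, nB: int, k: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(M, nA, nB)."""
    if not (0 <= k <= min(nA, nB) <= max(nA, nB) <= M):
        raise ValueError(f"impossible configuration M={M}, nA={nA}, nB={nB}, k={k}")
    if k == 0:
        return 1.0
    return float(min(1.0, stats.hypergeom.sf(k - 1, M, nA, nB)))


def pair_coexpression(expr_a, expr_b) -> tuple[float, float]:
    """Pearson correlation and its two-sided p-value over paired samples.

    Returns (nan, nan) when either vector has zero variance; callers treat
    that as a failed co-expression filter.
    """
    a = np.asarray(expr_a, dtype=float)
    b = np.asarray(expr_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("expression vectors must be 1-D and paired")
    if a.size < 3:
        raise ValueError("co-expression requires >= 3 paired samples")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan"), float("nan")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)


def target_mirna_sets(interactions: pd.DataFrame) -> tuple[dict, dict, int]:
    """(lncRNA -> miRNA set, mRNA -> miRNA set, universe size M)."""
    required = {"mirna_id", "target_id", "target_type"}
    if not required.issubset(interactions.columns):
        raise ValueError(f"interaction table needs columns {sorted(required)}")
    dedup = interactions.drop_duplicates(["mirna_id", "target_id"])
    lnc: dict[str, set] = {}
    mrna: dict[str, set] = {}
    for mir, tgt, ttype in dedup[["mirna_id", "target_id", "target_type"]].itertuples(index=False):
        d = lnc if ttype == "lncRNA" else mrna
        d.setdefault(tgt, set()).add(mir)
    M = dedup["mirna_id"].nunique()
    return lnc, mrna, M


def call_cerna_pairs(interactions: pd.DataFrame,
                     expression: pd.DataFrame | None,
                     thresholds: CeRNAThresholds = CeRNAThresholds()
                     ) -> pd.DataFrame:
    """Score every lncRNA x mRNA pair with at least one shared miRNA.

    Returns one row per scored pair with k, set sizes, hypergeometric p,
    BH FDR over scored pairs, co-expression r and its p-value, and the
    ``passed`` flag. ``expression`` rows are feature ids, columns samples;
    pairs with a member absent from the expression matrix (or with zero
    variance) fail the co-expression criterion.
    """
    lnc_sets, mrna_sets, M = target_mirna_sets(interactions)
    if interactions.empty or M == 0:
        return _empty_pairs()

    # invert once so only pairs with k >= 1 are enumerated
    pair_k: dict[tuple[str, str], int] = {}
    by_mirna_lnc: dict[str, list[str]] = {}
    by_mirna_mrna: dict[str, list[str]] = {}
    for tgt, mirs in lnc_sets.items():
        for m in mirs:
            by_mirna_lnc.setdefault(m, []).append(tgt)
    for tgt, mirs in mrna_sets.items():
        for m in mirs:
            by_mirna_mrna.setdefault(m, []).append(tgt)
    for m, lncs in by_mirna_lnc.items():
        for l in lncs:
            for g in by_mirna_mrna.get(m, ()):
                pair_k[(l, g)] = pair_k.get((l, g), 0) + 1
    if not pair_k:
        return _empty_pairs()

    rows = []
    for (l, g), k in sorted(pair_k.items()):
        nA, nB = len(lnc_sets[l]), len(mrna_sets[g])
        p = hypergeom_pvalue(M, nA, nB, k)
        if expression is not None and l in expression.index and g in expression.index:
            r, rp = pair_coexpression(expression.loc[l].to_numpy(),
                                      expression.loc[g].to_numpy())
        else:
            r, rp = float("nan"), float("nan")
        rows.append((l, g, k, nA, nB, p, r, rp))
    df = pd.DataFrame(rows, columns=["lncrna_id", "mrna_id", "k", "n_lncrna",
                                     "n_mrna", "p_hyper", "r", "r_pvalue"])
    df["fdr"] = bh_adjust(df["p_hyper"].to_numpy())
    t = thresholds
    coexpr_ok = (df["r"] >= t.r_min) & (df["r_pvalue"] < t.r_p_max)
    coexpr_ok = coexpr_ok.fillna(False)
    df["passed"] = ((df["k"] > t.shared_min)
                    & (df["p_hyper"] < t.p_max)
                    & (df["fdr"] < t.fdr_max)
                    & coexpr_ok)
    return df[["lncrna_id", "mrna_id", "k", "n_lncrna", "n_mrna",
               "p_hyper", "fdr", "r", "r_pvalue", "passed"]]


def _empty_pairs() -> pd.DataFrame:
    return pd.DataFrame(columns=["lncrna_id", "mrna_id", "k", "n_lncrna",
                                 "n_mrna", "p_hyper", "fdr", "r", "r_pvalue",
                                 "passed"])


def extract_differential_network(pairs: pd.DataFrame,
                                 interactions: pd.DataFrame,
                                 de_status: Mapping[str, str]) -> nx.Graph:
    """Differential triplet network from passed pairs.

    A triplet enters the network iff its pair passed, the miRNA targets both
    the lncRNA and the mRNA, and lncRNA, miRNA and mRNA all have de_status
    'up' or 'down' (ids missing from ``de_status`` count as 'ns'). Nodes
    carry node_type and regulation; edges carry edge_type.
    """
    lnc_sets, mrna_sets, _ = target_mirna_sets(interactions)
    status = lambda i: de_status.get(i, "ns")  # noqa: E731
    g = nx.Graph()
    passed = pairs.loc[pairs["passed"]] if len(pairs) else pairs
    for l, m in passed[["lncrna_id", "mrna_id"]].itertuples(index=False) if len(passed) else []:
        if status(l) == "ns" or status(m) == "ns":
            continue
        shared = sorted(lnc_sets.get(l, set()) & mrna_sets.get(m, set()))
        de_mirs = [mir for mir in shared if status(mir) != "ns"]
        if not de_mirs:
            continue
        g.add_node(l, node_type="lncRNA", regulation=status(l))
        g.add_node(m, node_type="mRNA", regulation=status(m))
        g.add_edge(l, m, edge_type="lncRNA-mRNA_cerna")
        for mir in de_mirs:
            g.add_node(mir, node_type="miRNA", regulation=status(mir))
            g.add_edge(l, mir, edge_type="lncRNA-miRNA")
            g.add_edge(mir, m, edge_type="miRNA-mRNA")
    return g


class CeRNAResults:
    """Scored pair table plus network extraction helpers."""

    def __init__(self, pairs: pd.DataFrame, interactions: pd.DataFrame,
                 thresholds: CeRNAThresholds) -> None:
        self.pairs = pairs
        self.interactions = interactions
        self.thresholds = thresholds

    @property
    def passed_pairs(self) -> pd.DataFrame:
        return self.pairs.loc[self.pairs["passed"]]

    def differential_network(self, de_status: Mapping[str, str]) -> nx.Graph:
        return extract_differential_network(self.pairs, self.interactions,
                                            de_status)

    def summary(self) -> str:
        t = self.thresholds
        return "\n".join([
            "ceRNA pair inference (shared-miRNA hypergeometric test)",
            f"  scored pairs: {len(self.pairs)}",
            f"  rule:         k > {t.shared_min}, p < {t.p_max:g}, "
            f"FDR < {t.fdr_max:g}, r >= {t.r_min:g} (p < {t.r_p_max:g})",
            f"  passed:       {len(self.passed_pairs)}",
        ])

    def to_tsv(self, path: str | Path) -> None:
        self.pairs.to_csv(path, sep="\t", index=False, float_format="%.6g")


class CeRNAModel:
    """Model object: interaction table + expression matrix.

    With ``log_transform`` (default) co-expression is computed on
    log2(x + 1)-transformed expression, the usual scale for correlation of
    RNA-seq abundances; linear-scale Pearson is dominated by the largest
    counts.
    """

    def __init__(self, interactions: pd.DataFrame,
                 expression: pd.DataFrame | None = None,
                 thresholds: CeRNAThresholds = CeRNAThresholds(),
                 log_transform: bool = True) -> None:
        self.interactions = interactions
        if expression is not None and log_transform:
            expression = np.log2(expression + 1.0)
        self.expression = expression
        self.thresholds = thresholds

    def fit(self) -> CeRNAResults:
        pairs = call_cerna_pairs(self.interactions, self.expression,
                                 self.thresholds)
        return CeRNAResults(pairs, self.interactions, self.thresholds)
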