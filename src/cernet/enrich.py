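"""Over-representation test for term -> gene annotations (GO/pathway style).

Classic per-term upper-tail hypergeometric test: with a universe of N genes,
a term annotating n of them and a query of q genes of which x fall in the
term, p = P(X >= x), X ~ Hypergeometric(N, n, q). BH FDR is computed across
the tested terms. Graph-aware decorrelation (topGO elim/weight) is out of
scope; this is the plain test used for descriptive top-k reporting.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust

__all__ = ["enrichment_test", "top_terms", "read_term_map"]


def read_term_map(path: str | Path,
                  names_path: str | Path | None = None) -> pd.DataFrame:
    """Read a term map TSV (term_id, gene_id[, namespace]) with an optional
    name sidecar (term_id, term_name)."""
    df = pd.read_csv(path, sep="\t")
    if "namespace" not in df.columns:
        df["namespace"] = "default"
    if names_path is not None:
        names = pd.read_csv(names_path, sep="\t")
        df = df.merge(names, on="term_id", how="left")
    if "term_name" not in df.columns:
        df["term_name"] = df["term_id"]
    return df


def enrichment_test(query: set[str] | list[str], term_map: pd.DataFrame,
                    universe: set[str] | list[str]) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each term.

    ``term_map`` columns: term_id, gene_id, and optionally term_name /
    namespace. Terms are intersected with the universe before testing; the
    query must be a subset of the universe.
    """
    universe = set(universe)
    query = set(query)
    if not universe:
        raise ValueError("empty universe")
    if not query:
        raise ValueError("empty query")
    if not query <= universe:
        extra = sorted(query - universe)[:5]
        raise ValueError(f"query genes outside the universe, e.g. {extra}")
    tm = term_map.loc[term_map["gene_id"].isin(universe)]
    if "term_name" not in tm.columns:
        tm = tm.assign(term_name=tm["term_id"])
    if "namespace" not in tm.columns:
        tm = tm.assign(namespace="default")

    N, q = len(universe), len(query)
    rows = []
    for term_id, grp in tm.groupby("term_id", sort=True):
        genes = set(grp["gene_id"])
        n = len(genes)
        x = len(genes & query)
        p = 1.0 if x == 0 else float(min(1.0, stats.hypergeom.sf(x - 1, N, n, q)))
        rows.append((term_id, grp["term_name"].iloc[0],
                     grp["namespace"].iloc[0], x, n, q, N, p))
    df = pd.DataFrame(rows, columns=["term_id", "term_name", "namespace",
                                     "n_query_in_term", "n_term", "n_query",
                                     "n_universe", "p_value"])
    if len(df):
        df["fdr"] = bh_adjust(df["p_value"].to_numpy())
    else:
        df["fdr"] = []
    return df


def top_terms(results: pd.DataFrame, k: int = 20,
              namespace: str | None = None) -> pd.DataFrame:
    """Top-k terms by ascending p-value (ties by term_id), optionally within
    one namespace; returns min(k, n) rows."""
    if k < 1:
        raise ValueError("k must be >= 1")
    df = results
    if namespace is not None:
        df = df.loc[df["namespace"] == namespace]
    df = df.sort_values(["p_value", "term_id"], kind="mergesort")
    return df.head(k).reset_index(drop=True)
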