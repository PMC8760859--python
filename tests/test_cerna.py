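from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from cernet.cerna import (CeRNAModel, call_cerna_pairs,
                          extract_differential_network, hypergeom_pvalue,
                          pair_coexpression, shared_mirna_count)


class TestSharedCount:
    def test_partial_overlap(self):
        a = {f"m{i}" for i in range(1, 6)}
        b = {f"m{i}" for i in range(3, 9)}
        assert shared_mirna_count(a, b) == 3

    def test_disjoint_and_identical(self):
        assert shared_mirna_count({"a"}, {"b"}) == 0
        s = {f"m{i}" for i in range(7)}
        assert shared_mirna_count(s, s) == 7


def brute_force_upper_tail(M, nA, nB, k):
    """Enumerate every nB-subset of the universe and count overlaps >= k."""
    A = set(range(nA))
    hits = total = 0
    for B in combinations(range(M), nB):
        total += 1
        if len(A & set(B)) >= k:
            hits += 1
    return hits / total


class TestHypergeom:
    def test_full_overlap_of_five_in_ten(self):
        assert hypergeom_pvalue(10, 5, 5, 5) == pytest.approx(1 / 252)

    def test_small_case(self):
        assert hypergeom_pvalue(4, 2, 2, 1) == pytest.approx(5 / 6)

    def test_k_zero_is_certain(self):
        assert hypergeom_pvalue(30, 4, 7, 0) == 1.0

    @pytest.mark.parametrize("M,nA,nB,k", [
        (5, 6, 3, 1), (5, 3, 3, 4), (5, 3, 6, 1),
    ])
    def test_impossible_configurations_rejected(self, M, nA, nB, k):
        with pytest.raises(ValueError):
            hypergeom_pvalue(M, nA, nB, k)

    def test_matches_enumeration_small_universes(self):
        for M in range(1, 9):
            for nA in range(M + 1):
                for nB in range(M + 1):
                    for k in range(min(nA, nB) + 1):
                        assert hypergeom_pvalue(M, nA, nB, k) == pytest.approx(
                            brute_force_upper_tail(M, nA, nB, k)), (M, nA, nB, k)

    @given(st.integers(1, 40).flatmap(
        lambda M: st.tuples(st.just(M), st.integers(0, M), st.integers(0, M))))
    def test_monotone_in_k_and_symmetric(self, cfg):
        M, nA, nB = cfg
        ps = [hypergeom_pvalue(M, nA, nB, k) for k in range(min(nA, nB) + 1)]
        assert all(a >= b - 1e-12 for a, b in zip(ps, ps[1:]))
        for k in range(min(nA, nB) + 1):
            assert hypergeom_pvalue(M, nA, nB, k) == pytest.approx(
                hypergeom_pvalue(M, nB, nA, k))


class TestCoexpression:
    def test_perfect_linear(self):
        x = np.array([1.0, 2, 3, 4, 5])
        r, p = pair_coexpression(x, 2 * x)
        assert r == pytest.approx(1.0)
        assert p < 0.05

    def test_perfect_anticorrelation(self):
        x = np.array([1.0, 2, 3, 4])
        r, _ = pair_coexpression(x, -x + 10)
        assert r == pytest.approx(-1.0)

    def test_independent_vectors_near_zero(self):
        rng = np.random.default_rng(0)
        r, _ = pair_coexpression(rng.normal(size=1000), rng.normal(size=1000))
        assert abs(r) < 0.1

    def test_zero_variance_is_nan(self):
        r, p = pair_coexpression([1.0, 1, 1], [1.0, 2, 3])
        assert np.isnan(r) and np.isnan(p)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            pair_coexpression([1.0, 2], [3.0, 4])


def _toy_interactions(k_shared=6, M=40):
    """One lncRNA-mRNA pair sharing k_shared miRNAs in a universe of M."""
    rows = []
    for i in range(k_shared):
        rows.append((f"miR{i:03d}", "LNC1", "lncRNA"))
        rows.append((f"miR{i:03d}", "GENE1", "mRNA"))
    for i in range(k_shared, M):  # pad the universe with unrelated edges
        rows.append((f"miR{i:03d}", f"GENE{i}", "mRNA"))
    return pd.DataFrame(rows, columns=["mirna_id", "target_id", "target_type"])


def _expr(corr: bool):
    base = np.linspace(1, 40, 12)
    other = base * 1.5 if corr else np.array(
        [5, 30, 8, 28, 12, 25, 15, 22, 18, 20, 35, 2.0])
    return pd.DataFrame([base, other], index=["LNC1", "GENE1"],
                        columns=[f"s{i}" for i in range(12)])


class TestCallPairs:
    def test_coexpression_failure_blocks_pair(self):
        pairs = call_cerna_pairs(_toy_interactions(), _expr(corr=False))
        row = pairs.set_index(["lncrna_id", "mrna_id"]).loc[("LNC1", "GENE1")]
        assert row["k"] == 6
        assert row["p_hyper"] < 0.01 and row["fdr"] < 0.01
        assert not row["passed"]

    def test_full_rule_passes(self):
        pairs = call_cerna_pairs(_toy_interactions(), _expr(corr=True))
        row = pairs.set_index(["lncrna_id", "mrna_id"]).loc[("LNC1", "GENE1")]
        assert row["passed"]

    def test_shared_min_is_strict(self):
        pairs = call_cerna_pairs(_toy_interactions(k_shared=5), _expr(corr=True))
        row = pairs.set_index(["lncrna_id", "mrna_id"]).loc[("LNC1", "GENE1")]
        assert row["k"] == 5 and not row["passed"]

    def test_missing_expression_fails_filter(self):
        pairs = call_cerna_pairs(_toy_interactions(), expression=None)
        assert not pairs["passed"].any()

    def test_empty_table_gives_empty_result(self):
        empty = pd.DataFrame(columns=["mirna_id", "target_id", "target_type"])
        assert len(call_cerna_pairs(empty, None)) == 0

    def test_k_bounded_by_set_sizes(self, small_dataset):
        pairs = CeRNAModel(small_dataset.interactions).fit().pairs
        assert (pairs["k"] <= pairs[["n_lncrna", "n_mrna"]].min(axis=1)).all()


class TestDifferentialNetwork:
    interactions = _toy_interactions()
    pairs = call_cerna_pairs(interactions, _expr(corr=True))

    def status(self, mir="up"):
        s = {"LNC1": "up", "GENE1": "down"}
        for i in range(6):
            s[f"miR{i:03d}"] = mir
        return s

    def test_full_triplet_retained_with_attributes(self):
        g = extract_differential_network(self.pairs, self.interactions,
                                         self.status())
        assert g.nodes["LNC1"] == {"node_type": "lncRNA", "regulation": "up"}
        assert g.nodes["GENE1"]["regulation"] == "down"
        assert g["LNC1"]["GENE1"]["edge_type"] == "lncRNA-mRNA_cerna"
        assert g["LNC1"]["miR000"]["edge_type"] == "lncRNA-miRNA"
        assert g["miR000"]["GENE1"]["edge_type"] == "miRNA-mRNA"

    def test_ns_mirnas_drop_the_triplet(self):
        g = extract_differential_network(self.pairs, self.interactions,
                                         self.status(mir="ns"))
        assert g.number_of_nodes() == 0

    def test_empty_status_gives_empty_network(self):
        g = extract_differential_network(self.pairs, self.interactions, {})
        assert isinstance(g, nx.Graph) and g.number_of_nodes() == 0

    def test_edge_types_consistent_with_node_types(self, small_dataset):
        from cernet.normalize import normalized_counts
        from cernet.diffexpr import NegativeBinomialDE
        from cernet.simulate import _CONTRAST_ACL
        res = CeRNAModel(small_dataset.interactions,
                         normalized_counts(small_dataset.counts.counts)).fit()
        de = NegativeBinomialDE(small_dataset.counts,
                                small_dataset.design).fit(_CONTRAST_ACL)
        g = res.differential_network(de.de_status())
        assert g.number_of_nodes() > 0
        allowed = {frozenset(("lncRNA", "miRNA")): "lncRNA-miRNA",
                   frozenset(("miRNA", "mRNA")): "miRNA-mRNA",
                   frozenset(("lncRNA", "mRNA")): "lncRNA-mRNA_cerna"}
        for u, v, d in g.edges(data=True):
            key = frozenset((g.nodes[u]["node_type"], g.nodes[v]["node_type"]))
            assert allowed[key] == d["edge_type"]
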