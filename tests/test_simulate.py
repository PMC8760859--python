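import numpy as np
import pytest

from cernet.classify import classify_all
from cernet.normalize import normalized_counts
from cernet.simulate import (SimulationConfig, generate_annotation,
                             generate_counts, generate_interactions,
                             generate_qpcr, largest_remainder, make_design,
                             write_dataset)
from cernet.simulate import _CONTRAST_ACL
from cernet.cerna import target_mirna_sets, shared_mirna_count
from cernet.qpcr import ddct


class TestConfig:
    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            SimulationConfig(class_fractions=(0.5, 0.5, 0.5, 0.0))

    def test_k_shared_bounds(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_mirnas=7, k_shared=8)
        with pytest.raises(ValueError):
            SimulationConfig(k_shared=5, shared_min=5)


class TestLargestRemainder:
    def test_study_fractions(self):
        assert largest_remainder((0.4, 0.088, 0.488, 0.024), 100) == [40, 9, 49, 2]

    def test_degenerate(self):
        assert largest_remainder((1.0, 0.0, 0.0, 0.0), 4) == [4, 0, 0, 0]

    def test_total_preserved(self):
        for n in (1, 7, 83, 250):
            assert sum(largest_remainder((0.4, 0.088, 0.488, 0.024), n)) == n


class TestAnnotationGeneration:
    def test_class_counts_match_largest_remainder(self):
        ann = generate_annotation(SimulationConfig(seed=2))
        counts = {c: sum(t.true_class == c for t in ann.lncrnas)
                  for c in ("lincRNA", "antisense", "intronic", "sense")}
        assert counts == {"lincRNA": 40, "antisense": 9,
                          "intronic": 49, "sense": 2}

    def test_round_trip_classification(self):
        ann = generate_annotation(SimulationConfig(seed=3))
        results = classify_all(ann.lncrnas, ann.genes)
        assert all(r.lncrna_class == t.true_class
                   for r, t in zip(results, ann.lncrnas))

    def test_all_linc_fraction_never_overlaps_genes(self):
        cfg = SimulationConfig(n_lncrnas=4, class_fractions=(1, 0, 0, 0),
                               seed=4)
        ann = generate_annotation(cfg)
        assert len(ann.lncrnas) == 4
        for r in classify_all(ann.lncrnas, ann.genes):
            assert r.lncrna_class == "lincRNA"

    def test_gtf_byte_identical_across_calls(self, tmp_path):
        from cernet.annotation import write_gtf
        cfg = SimulationConfig(seed=5)
        for name in ("a.gtf", "b.gtf"):
            write_gtf(generate_annotation(cfg), tmp_path / name)
        assert (tmp_path / "a.gtf").read_bytes() == (tmp_path / "b.gtf").read_bytes()


class TestCounts:
    def test_same_seed_identical(self):
        cfg = SimulationConfig(seed=6)
        ann = generate_annotation(cfg)
        c1, _ = generate_counts(ann, cfg)
        c2, _ = generate_counts(ann, cfg)
        assert c1.counts.equals(c2.counts)

    def test_null_log_ratio_shrinks_with_replicates(self):
        cfg = SimulationConfig(seed=7, n_replicates=50, n_de_features=0,
                               n_triplets=0, n_genes=50, n_lncrnas=4,
                               n_mirnas=6, k_shared=6)
        ann = generate_annotation(cfg)
        cm, truth = generate_counts(ann, cfg)
        assert truth.de_features == {}
        design = make_design(cfg)
        norm = normalized_counts(cm.counts)
        inj = design.index[(design.tissue == "ACL") & (design.condition == "injured")]
        nor = design.index[(design.tissue == "ACL") & (design.condition == "normal")]
        ratio = np.log2(norm[list(inj)].mean(axis=1) / norm[list(nor)].mean(axis=1))
        assert np.abs(ratio).mean() < 0.1

    def test_poisson_limit_variance_over_mean(self):
        base = dict(n_genes=2, n_lncrnas=1, class_fractions=(0, 0, 1, 0),
                    n_mirnas=6, k_shared=6, n_triplets=0, n_de_features=0,
                    n_replicates=2500, mean_count=200.0, seed=8)
        ratios = {}
        for disp in (0.0, 0.1):
            cfg = SimulationConfig(nb_dispersion=disp, **base)
            ann = generate_annotation(cfg)
            cm, _ = generate_counts(ann, cfg)
            design = make_design(cfg)
            grp = design.index[(design.tissue == "MCL")
                               & (design.condition == "normal")]
            norm = normalized_counts(cm.counts)[list(grp)]
            feat = norm.iloc[0]
            ratios[disp] = feat.var(ddof=1) / feat.mean()
        assert ratios[0.0] < 1.3          # Poisson limit
        assert ratios[0.1] > 5.0          # strongly overdispersed at m~200

    def test_planted_effect_calibration(self):
        cfg = SimulationConfig(seed=9, n_replicates=10, n_triplets=0)
        ann = generate_annotation(cfg)
        cm, truth = generate_counts(ann, cfg)
        design = make_design(cfg)
        norm = normalized_counts(cm.counts)
        inj = list(design.index[(design.tissue == "ACL")
                                & (design.condition == "injured")])
        nor = list(design.index[(design.tissue == "ACL")
                                & (design.condition == "normal")])
        planted = truth.planted_for(_CONTRAST_ACL)
        emp = np.log2(norm.loc[list(planted), inj].mean(axis=1)
                      / norm.loc[list(planted), nor].mean(axis=1))
        diffs = emp.to_numpy() - np.array([planted[f] for f in emp.index])
        se = diffs.std(ddof=1) / np.sqrt(len(diffs))
        assert abs(diffs.mean()) < 3 * se


class TestInteractions:
    def test_planted_pairs_share_exactly_k(self):
        cfg = SimulationConfig(seed=10, k_shared=8)
        ann = generate_annotation(cfg)
        inter, truth = generate_interactions(ann, cfg)
        lnc, mrna, _ = target_mirna_sets(inter)
        for l, shared, g in truth.cerna_triplets:
            assert shared_mirna_count(lnc[l], mrna[g]) == 8
            assert set(shared) <= lnc[l] and set(shared) <= mrna[g]

    def test_sparse_background_has_no_high_overlap(self):
        cfg = SimulationConfig(seed=12, n_triplets=0, bg_targets_mrna=2,
                               bg_targets_lncrna=2)
        ann = generate_annotation(cfg)
        inter, _ = generate_interactions(ann, cfg)
        lnc, mrna, _ = target_mirna_sets(inter)
        worst = max(shared_mirna_count(a, b)
                    for a in lnc.values() for b in mrna.values())
        assert worst <= 5

    def test_same_seed_identical(self):
        cfg = SimulationConfig(seed=13)
        ann = generate_annotation(cfg)
        t1, _ = generate_interactions(ann, cfg)
        t2, _ = generate_interactions(ann, cfg)
        assert t1.equals(t2)


class TestQpcr:
    def test_noise_free_fold_is_exact(self):
        cfg = SimulationConfig(seed=14, qpcr_noise_sd=0.0,
                               qpcr_effects=(("TGT1", 4.0),))
        rel = ddct(generate_qpcr(cfg), "ACTB", "control")
        case = rel.loc[rel.group == "case", "fold"]
        assert np.allclose(case, 4.0)

    def test_null_fold_near_one(self):
        cfg = SimulationConfig(seed=15, qpcr_effects=(("TGT1", 1.0),),
                               n_qpcr_samples=6)
        rel = ddct(generate_qpcr(cfg), "ACTB", "control")
        assert abs(rel.loc[rel.group == "case", "fold"].mean() - 1.0) < 0.25

    def test_same_seed_identical(self):
        cfg = SimulationConfig(seed=16)
        assert generate_qpcr(cfg).equals(generate_qpcr(cfg))


class TestDatasetIO:
    def test_write_dataset_round_trips(self, tmp_path, small_dataset):
        from cernet.normalize import CountMatrix
        from cernet.annotation import read_gtf
        from cernet.simulate import TruthSet
        paths = write_dataset(small_dataset, tmp_path)
        cm = CountMatrix.from_tsv(paths["counts"])
        assert cm.counts.equals(small_dataset.counts.counts)
        ann = read_gtf(paths["annotation"])
        assert ann.lncrnas == small_dataset.annotation.lncrnas
        truth = TruthSet.from_json(paths["truth"])
        assert truth.triplet_pairs() == small_dataset.truth.triplet_pairs()

    def test_truth_partition(self, small_dataset):
        truth = small_dataset.truth
        ids = set(small_dataset.counts.counts.index)
        assert set(truth.de_features).isdisjoint(truth.null_features)
        assert set(truth.de_features) | set(truth.null_features) == ids
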