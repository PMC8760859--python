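"""Seeded synthetic-data generator for the full pipeline.

Emulates a 2-tissue (ACL, MCL) x 2-condition (normal, injured) bulk RNA-seq
study: a single-chromosome gene annotation with lncRNAs placed to realize
the four positional classes, negative-binomial counts with per-sample size
factors and planted fold changes, a miRNA->target interaction table with
planted ceRNA triplets whose members share a fixed number of miRNAs and are
co-expressed through a shared latent factor, a PPI edge list, a term->gene
map, and a qPCR Ct table. Everything is a pure function of
(config, config.seed): repeated calls are byte-identical on disk.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import (GenomeAnnotation, GeneModel, TranscriptModel,
                         feature_lengths, iter_features, write_gtf)
from .classify import classify_lncrna
from .normalize import CountMatrix

__all__ = ["SimulationConfig", "TruthSet", "SyntheticDataset",
           "largest_remainder", "make_design", "generate_annotation",
           "generate_counts", "generate_interactions", "generate_ppi",
           "generate_term_map", "generate_qpcr", "generate_dataset",
           "write_dataset"]

TISSUES = ("ACL", "MCL")
CONDITIONS = ("normal", "injured")

_STREAMS = {"annotation": 1, "counts": 2, "interactions": 3, "qpcr": 4,
            "ppi": 5, "terms": 6}


def _rng(config: "SimulationConfig", stage: str) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), _STREAMS[stage]])


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the generator.

    Defaults mirror the emulated study: four lncRNA positional classes at
    40/8.8/48.8/2.4%, two replicates per tissue-condition group (the
    sequencing design), NB dispersion 0.1 (variance m + 0.1 m^2), planted
    |log2FC| of 2 (the calling threshold's effect scale), and ceRNA triplets
    sharing k_shared = 8 miRNAs (above the >5 rule).
    """

    n_genes: int = 200
    n_lncrnas: int = 100
    n_mirnas: int = 150
    class_fractions: tuple[float, float, float, float] = (0.40, 0.088, 0.488, 0.024)
    n_replicates: int = 2
    nb_dispersion: float = 0.1
    planted_log2fc: float = 2.0
    mean_count: float = 200.0
    seed: int = 0
    # planted structure
    n_de_features: int = 40        # per planted contrast set
    n_triplets: int = 10
    k_shared: int = 8
    shared_min: int = 5
    coexpr_sd: float = 1.5         # ln-scale sd of the shared latent factor
    # interaction background (exact per-miRNA target counts)
    bg_targets_mrna: int = 4
    bg_targets_lncrna: int = 2
    # qPCR
    qpcr_effects: tuple[tuple[str, float], ...] = (
        ("TGT1", 4.0), ("TGT2", 0.25), ("TGT3", 1.0))
    qpcr_noise_sd: float = 0.15
    n_qpcr_samples: int = 3

    def __post_init__(self) -> None:
        if len(self.class_fractions) != 4 or any(f < 0 for f in self.class_fractions):
            raise ValueError("class_fractions must be 4 non-negative values")
        if abs(sum(self.class_fractions) - 1.0) > 1e-9:
            raise ValueError("class_fractions must sum to 1 within 1e-9")
        for name in ("n_genes", "n_lncrnas", "n_mirnas", "n_replicates"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be non-negative")
        if self.mean_count <= 0:
            raise ValueError("mean_count must be positive")
        if self.n_mirnas <= self.shared_min:
            raise ValueError("n_mirnas must exceed shared_min")
        if self.k_shared > self.n_mirnas:
            raise ValueError("k_shared cannot exceed n_mirnas")
        if self.k_shared <= self.shared_min:
            raise ValueError("k_shared must exceed shared_min")

    @property
    def mirna_ids(self) -> list[str]:
        return [f"miR{i + 1:04d}" for i in range(self.n_mirnas)]


@dataclass
class TruthSet:
    """Ground truth for recovery tests.

    ``de_features`` maps feature id -> {contrast name -> planted log2FC}
    (including effects induced in the between-tissue contrasts by
    injury-specific planting); ``cerna_triplets`` lists
    (lncRNA id, shared miRNA ids, mRNA id); ``null_features`` are ids with
    no planted effect in any contrast.
    """

    de_features: dict[str, dict[str, float]] = field(default_factory=dict)
    cerna_triplets: list[tuple[str, tuple[str, ...], str]] = field(default_factory=list)
    null_features: list[str] = field(default_factory=list)

    def planted_for(self, contrast_name: str) -> dict[str, float]:
        return {f: c[contrast_name] for f, c in self.de_features.items()
                if contrast_name in c}

    def triplet_pairs(self) -> set[tuple[str, str]]:
        return {(l, g) for l, _, g in self.cerna_triplets}

    def to_json(self, path: str | Path) -> None:
        obj = {"de_features": self.de_features,
               "cerna_triplets": [[l, list(m), g] for l, m, g in self.cerna_triplets],
               "null_features": self.null_features}
        Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthSet":
        obj = json.loads(Path(path).read_text())
        return cls(de_features=obj["de_features"],
                   cerna_triplets=[(l, tuple(m), g)
                                   for l, m, g in obj["cerna_triplets"]],
                   null_features=obj["null_features"])


def largest_remainder(fractions, n: int) -> list[int]:
    """Integer apportionment of n among fractions (largest-remainder rule,
    ties by position)."""
    raw = [f * n for f in fractions]
    base = [math.floor(r) for r in raw]
    leftover = n - sum(base)
    order = sorted(range(len(raw)), key=lambda i: (-(raw[i] - base[i]), i))
    for i in order[:leftover]:
        base[i] += 1
    return base


def make_design(config: SimulationConfig) -> pd.DataFrame:
    """Sample design table: 2 tissues x 2 conditions x n_replicates."""
    rows = [(f"{t}_{c}_{r + 1}", t, c)
            for t in TISSUES for c in CONDITIONS
            for r in range(config.n_replicates)]
    return (pd.DataFrame(rows, columns=["sample_id", "tissue", "condition"])
            .set_index("sample_id"))


# ---------------------------------------------------------------- annotation

def generate_annotation(config: SimulationConfig) -> GenomeAnnotation:
    """Single-chromosome annotation realizing the configured class counts.

    Genes are spaced >= 12 kb apart so each lncRNA's positional class is
    unambiguous; class counts follow largest-remainder rounding of the
    configured fractions. Placement by construction: lincRNAs >= 5 kb from
    any gene, antisense/sense overlapping an exon on the opposite/same
    strand, intronic strictly inside an intron.
    """
    n_linc, n_anti, n_intr, n_sense = largest_remainder(
        config.class_fractions, config.n_lncrnas)
    if n_linc > max(config.n_genes - 1, 0):
        raise ValueError("not enough intergenic gaps for the lincRNA count; "
                         "increase n_genes")
    if n_anti + n_intr + n_sense > config.n_genes:
        raise ValueError("not enough host genes for the gene-overlapping "
                         "lncRNA classes; increase n_genes")

    rng = _rng(config, "annotation")
    chrom = "chr1"
    genes: list[GeneModel] = []
    cursor = 10_000
    for i in range(config.n_genes):
        n_exons = int(rng.integers(2, 5))
        exon_lens = rng.integers(150, 401, n_exons)
        intron_lens = rng.integers(800, 2001, n_exons - 1)
        exons = []
        pos = cursor
        for j, el in enumerate(exon_lens):
            exons.append((pos, pos + int(el) - 1))
            pos = exons[-1][1] + 1
            if j < n_exons - 1:
                pos += int(intron_lens[j])
        strand = "+" if rng.integers(2) == 0 else "-"
        genes.append(GeneModel(f"GENE{i + 1:05d}", chrom, strand,
                               exons[0][0], exons[-1][1], tuple(exons)))
        cursor = exons[-1][1] + 1 + 12_000 + int(rng.integers(0, 6001))

    lncrnas: list[TranscriptModel] = []
    counter = 0

    def add(start: int, end: int, strand: str, true_class: str) -> None:
        nonlocal counter
        counter += 1
        lncrnas.append(TranscriptModel(f"LNC{counter:05d}", chrom, strand,
                                       start, end, ((start, end),), true_class))

    # lincRNAs: one per selected intergenic gap, >= 5 kb from both neighbors
    gap_idx = sorted(rng.choice(config.n_genes - 1, size=n_linc,
                                replace=False)) if n_linc else []
    for gi in gap_idx:
        left, right = genes[gi], genes[gi + 1]
        available = right.start - left.end - 1 - 10_000
        length = int(min(rng.integers(300, 1501), available))
        offset = int(rng.integers(0, available - length + 1))
        start = left.end + 5_001 + offset
        add(start, start + length - 1,
            "+" if rng.integers(2) == 0 else "-", "lincRNA")

    hosts = rng.permutation(config.n_genes)
    k = 0
    for _ in range(n_anti):
        g = genes[hosts[k]]; k += 1
        es, ee = g.exons[int(rng.integers(len(g.exons)))]
        start = es + (ee - es) // 2
        length = int(rng.integers(300, 801))
        add(start, start + length - 1, "-" if g.strand == "+" else "+",
            "antisense")
    for _ in range(n_intr):
        g = genes[hosts[k]]; k += 1
        isv, iev = g.introns[int(rng.integers(len(g.introns)))]
        room = iev - isv + 1 - 2            # strict containment, pad 1 bp
        length = int(rng.integers(200, min(600, room) + 1))
        start = isv + 1 + int(rng.integers(0, room - length + 1))
        add(start, start + length - 1,
            "+" if rng.integers(2) == 0 else "-", "intronic")
    for _ in range(n_sense):
        g = genes[hosts[k]]; k += 1
        es, ee = g.exons[int(rng.integers(len(g.exons)))]
        start = es + (ee - es) // 2
        length = int(rng.integers(300, 801))
        add(start, start + length - 1, g.strand, "sense")

    ann = GenomeAnnotation(genes=genes, lncrnas=lncrnas)
    for t in ann.lncrnas:  # construction guarantees the round-trip
        got = classify_lncrna(t, ann.genes).lncrna_class
        if got != t.true_class:
            raise RuntimeError(
                f"placement bug: {t.transcript_id} built as {t.true_class} "
                f"but classifies as {got}")
    return ann


# -------------------------------------------------------------------- counts

_CONTRAST_ACL = "tissue=ACL:condition=injured-vs-normal"
_CONTRAST_MCL = "tissue=MCL:condition=injured-vs-normal"
_CONTRAST_NORMAL = "condition=normal:tissue=ACL-vs-MCL"
_CONTRAST_INJURED = "condition=injured:tissue=ACL-vs-MCL"
DEFAULT_CONTRASTS = (_CONTRAST_ACL, _CONTRAST_MCL,
                     _CONTRAST_NORMAL, _CONTRAST_INJURED)


def generate_counts(annotation: GenomeAnnotation, config: SimulationConfig,
                    triplets: list[tuple[str, tuple[str, ...], str]] | None = None
                    ) -> tuple[CountMatrix, TruthSet]:
    """NB counts for the 2x2 design with planted fold changes.

    Three disjoint planted sets (ACL injury response, MCL injury response,
    constitutive tissue difference) receive |log2FC| = planted_log2fc with
    random sign. Planted ceRNA triplet members are up/down-co-regulated in
    the ACL injury response (lncRNA and mRNA with the same sign, their shared
    miRNAs with the opposite sign) and share a per-sample latent factor so
    the co-expression filter has signal. Per-sample size factors are drawn
    log-uniform in [0.5, 2].
    """
    if config.n_replicates < 2:
        raise ValueError("n_replicates must be >= 2")
    rng = _rng(config, "counts")
    design = make_design(config)
    samples = list(design.index)
    n_samples = len(samples)

    features = list(iter_features(annotation))
    lengths = feature_lengths(annotation)
    for mir in config.mirna_ids:
        features.append((mir, "miRNA"))
        lengths[mir] = 22
    ids = [f for f, _ in features]
    types = {f: t for f, t in features}

    base = config.mean_count * rng.lognormal(0.0, 0.6, len(ids))

    triplets = triplets or []
    member_ids = {x for l, mirs, g in triplets for x in (l, g, *mirs)}
    eligible = [f for f, t in features if t != "miRNA" and f not in member_ids]
    perm = list(rng.permutation(len(eligible)))
    need = 3 * config.n_de_features
    if len(eligible) < need:
        raise ValueError(f"not enough features to plant 3 x "
                         f"{config.n_de_features} effects ({len(eligible)})")
    picks = [eligible[i] for i in perm[:need]]
    s_acl = picks[:config.n_de_features]
    s_mcl = picks[config.n_de_features:2 * config.n_de_features]
    s_tissue = picks[2 * config.n_de_features:]

    lfc_acl = {f: 0.0 for f in ids}
    lfc_mcl = {f: 0.0 for f in ids}
    lfc_tissue = {f: 0.0 for f in ids}
    de: dict[str, dict[str, float]] = {}

    def sign() -> float:
        return 1.0 if rng.integers(2) == 0 else -1.0

    for f in s_acl:
        lfc_acl[f] = sign() * config.planted_log2fc
        de[f] = {_CONTRAST_ACL: lfc_acl[f], _CONTRAST_INJURED: lfc_acl[f]}
    for f in s_mcl:
        lfc_mcl[f] = sign() * config.planted_log2fc
        de[f] = {_CONTRAST_MCL: lfc_mcl[f], _CONTRAST_INJURED: -lfc_mcl[f]}
    for f in s_tissue:
        lfc_tissue[f] = sign() * config.planted_log2fc
        de[f] = {_CONTRAST_NORMAL: lfc_tissue[f],
                 _CONTRAST_INJURED: lfc_tissue[f]}
    for l, mirs, g in triplets:
        s = sign()
        for f in (l, g):
            lfc_acl[f] = s * config.planted_log2fc
            de[f] = {_CONTRAST_ACL: lfc_acl[f], _CONTRAST_INJURED: lfc_acl[f]}
        for mir in mirs:
            lfc_acl[mir] = -s * config.planted_log2fc
            de[mir] = {_CONTRAST_ACL: lfc_acl[mir],
                       _CONTRAST_INJURED: lfc_acl[mir]}

    # ln-scale latent factors shared within each planted triplet
    latent = np.zeros((len(ids), n_samples))
    idx = {f: i for i, f in enumerate(ids)}
    for l, _, g in triplets:
        z = rng.normal(0.0, config.coexpr_sd, n_samples)
        latent[idx[l]] += z
        latent[idx[g]] += z

    size = np.exp(rng.uniform(np.log(0.5), np.log(2.0), n_samples))
    ln2 = np.log(2.0)
    mu = np.empty((len(ids), n_samples))
    for j, s_id in enumerate(samples):
        t, c = design.loc[s_id, "tissue"], design.loc[s_id, "condition"]
        lfc = np.zeros(len(ids))
        if c == "injured":
            lf = lfc_acl if t == "ACL" else lfc_mcl
            lfc += np.array([lf[f] for f in ids])
        if t == "ACL":
            lfc += np.array([lfc_tissue[f] for f in ids])
        mu[:, j] = base * np.exp(ln2 * lfc + latent[:, j]) * size[j]

    if config.nb_dispersion <= 1e-8:
        counts = rng.poisson(mu)
    else:
        r = 1.0 / config.nb_dispersion
        counts = rng.negative_binomial(r, r / (r + mu))

    cm = CountMatrix(pd.DataFrame(counts.astype(np.int64), index=ids,
                                  columns=samples),
                     pd.Series([types[f] for f in ids], index=ids,
                               name="feature_type"),
                     pd.Series([lengths[f] for f in ids], index=ids,
                               name="length"))
    truth = TruthSet(de_features=de,
                     cerna_triplets=list(triplets),
                     null_features=sorted(set(ids) - set(de)))
    return cm, truth


# -------------------------------------------------------------- interactions

def generate_interactions(annotation: GenomeAnnotation,
                          config: SimulationConfig
                          ) -> tuple[pd.DataFrame, TruthSet]:
    """miRNA->target edges: uniform sparse background plus planted triplets.

    Each planted triplet's lncRNA and mRNA share exactly ``k_shared`` miRNAs;
    background edges that would inflate the pair's overlap are pruned.
    """
    rng = _rng(config, "interactions")
    mirnas = config.mirna_ids
    mrnas = [g.gene_id for g in annotation.genes]
    lncs = [t.transcript_id for t in annotation.lncrnas]
    if config.n_triplets > 0 and (len(lncs) < config.n_triplets
                                  or len(mrnas) < config.n_triplets):
        raise ValueError("not enough lncRNAs/mRNAs for the requested triplets")

    edges: set[tuple[str, str, str]] = set()
    for mir in mirnas:
        if config.bg_targets_mrna and mrnas:
            for t in rng.choice(mrnas, size=min(config.bg_targets_mrna,
                                                len(mrnas)), replace=False):
                edges.add((mir, str(t), "mRNA"))
        if config.bg_targets_lncrna and lncs:
            for t in rng.choice(lncs, size=min(config.bg_targets_lncrna,
                                               len(lncs)), replace=False):
                edges.add((mir, str(t), "lncRNA"))

    trip_lncs = [str(x) for x in rng.choice(lncs, config.n_triplets,
                                            replace=False)] if config.n_triplets else []
    trip_mrnas = [str(x) for x in rng.choice(mrnas, config.n_triplets,
                                             replace=False)] if config.n_triplets else []
    triplets = []
    for l, g in zip(trip_lncs, trip_mrnas):
        shared = tuple(sorted(str(m) for m in
                              rng.choice(mirnas, config.k_shared, replace=False)))
        for mir in shared:
            edges.add((mir, l, "lncRNA"))
            edges.add((mir, g, "mRNA"))
        # prune incidental background overlap so the pair shares exactly k_shared
        lnc_mirs = {m for m, t, _ in edges if t == l}
        mrna_mirs = {m for m, t, _ in edges if t == g}
        for mir in (lnc_mirs & mrna_mirs) - set(shared):
            edges.discard((mir, l, "lncRNA"))
        triplets.append((l, shared, g))

    df = (pd.DataFrame(sorted(edges),
                       columns=["mirna_id", "target_id", "target_type"])
          .reset_index(drop=True))
    truth = TruthSet(cerna_triplets=triplets)
    return df, truth


# ------------------------------------------------------------------ ppi/terms

def generate_ppi(annotation: GenomeAnnotation, config: SimulationConfig,
                 hub_genes: list[str] | None = None,
                 mean_degree: float = 4.0) -> pd.DataFrame:
    """Erdos-Renyi PPI background over the mRNAs, with a densely wired
    module among ``hub_genes`` (first 15) so hub ranking has structure."""
    rng = _rng(config, "ppi")
    genes = [g.gene_id for g in annotation.genes]
    n = len(genes)
    p = min(mean_degree / max(n - 1, 1), 1.0)
    edges = set()
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                edges.add((genes[i], genes[j]))
    module = sorted(hub_genes or [])[:15]
    for i in range(len(module)):
        for j in range(i + 1, len(module)):
            if rng.random() < 0.6:
                edges.add(tuple(sorted((module[i], module[j]))))
    return pd.DataFrame(sorted(edges), columns=["protein_a", "protein_b"])


def generate_term_map(annotation: GenomeAnnotation, config: SimulationConfig,
                      signal_genes: list[str] | None = None,
                      n_terms: int = 30) -> pd.DataFrame:
    """Random term->gene map with a few terms enriched in ``signal_genes``."""
    rng = _rng(config, "terms")
    genes = [g.gene_id for g in annotation.genes]
    namespaces = ("BP", "CC", "MF", "pathway")
    signal = sorted(set(signal_genes or []) & set(genes))
    rows = []
    for i in range(n_terms):
        term = f"TERM{i + 1:04d}"
        ns = namespaces[i % 4]
        size = int(rng.integers(10, min(51, len(genes) + 1)))
        if i < 3 and signal:
            n_sig = min(len(signal), max(1, int(round(size * 0.6))))
            members = set(str(x) for x in rng.choice(signal, n_sig, replace=False))
            rest = [g for g in genes if g not in members]
            members |= {str(x) for x in rng.choice(rest, size - len(members),
                                                   replace=False)}
        else:
            members = {str(x) for x in rng.choice(genes, size, replace=False)}
        for g in sorted(members):
            rows.append((term, g, ns, f"synthetic term {i + 1}"))
    return pd.DataFrame(rows, columns=["term_id", "gene_id", "namespace",
                                       "term_name"])


# --------------------------------------------------------------------- qPCR

def generate_qpcr(config: SimulationConfig,
                  reference_gene: str = "ACTB") -> pd.DataFrame:
    """Ct table for control/case groups with three technical replicates.

    Ct = gene baseline + per-sample loading offset - log2(relative
    expression) + Gaussian noise; the reference gene has relative expression
    1 everywhere, so offsets cancel in dCt and baselines in ddCt.
    """
    rng = _rng(config, "qpcr")
    genes = [(reference_gene, 1.0)] + [(g, f) for g, f in config.qpcr_effects]
    baselines = {reference_gene: float(rng.uniform(18, 22))}
    for g, _ in config.qpcr_effects:
        baselines[g] = float(rng.uniform(22, 30))
    rows = []
    for group, prefix in (("control", "C"), ("case", "K")):
        for s in range(config.n_qpcr_samples):
            sample = f"{prefix}{s + 1}"
            offset = float(rng.normal(0.0, 0.3))
            for gene, fold in genes:
                rel = fold if (group == "case" and gene != reference_gene) else 1.0
                for rep in range(1, 4):
                    noise = float(rng.normal(0.0, config.qpcr_noise_sd)) \
                        if config.qpcr_noise_sd > 0 else 0.0
                    ct = baselines[gene] + offset - math.log2(rel) + noise
                    rows.append((sample, group, gene, rep, ct))
    return pd.DataFrame(rows, columns=["sample_id", "group", "gene_id",
                                       "replicate", "ct"])


# ------------------------------------------------------------------ dataset

@dataclass
class SyntheticDataset:
    config: SimulationConfig
    annotation: GenomeAnnotation
    counts: CountMatrix
    design: pd.DataFrame
    interactions: pd.DataFrame
    ppi: pd.DataFrame
    term_map: pd.DataFrame
    ct: pd.DataFrame
    truth: TruthSet


def generate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate every pipeline input with a consistent merged truth set."""
    annotation = generate_annotation(config)
    interactions, trip_truth = generate_interactions(annotation, config)
    counts, truth = generate_counts(annotation, config,
                                    triplets=trip_truth.cerna_triplets)
    acl_de_mrnas = sorted(
        f for f, c in truth.de_features.items()
        if _CONTRAST_ACL in c and counts.feature_type.get(f) == "mRNA")
    ppi = generate_ppi(annotation, config, hub_genes=acl_de_mrnas)
    term_map = generate_term_map(annotation, config, signal_genes=acl_de_mrnas)
    ct = generate_qpcr(config)
    return SyntheticDataset(config, annotation, counts, make_design(config),
                            interactions, ppi, term_map, ct, truth)


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> dict[str, str]:
    """Write all inputs as plain-text files; returns name -> path."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "annotation": out / "annotation.gtf",
        "counts": out / "counts.tsv",
        "design": out / "design.tsv",
        "interactions": out / "interactions.tsv",
        "ppi": out / "ppi.tsv",
        "term_map": out / "term_map.tsv",
        "term_names": out / "term_names.tsv",
        "qpcr_ct": out / "qpcr_ct.tsv",
        "truth": out / "truth.json",
    }
    write_gtf(dataset.annotation, paths["annotation"])
    dataset.counts.to_tsv(paths["counts"])
    dataset.design.to_csv(paths["design"], sep="\t")
    dataset.interactions.to_csv(paths["interactions"], sep="\t", index=False)
    dataset.ppi.to_csv(paths["ppi"], sep="\t", index=False)
    dataset.term_map[["term_id", "gene_id", "namespace"]].to_csv(
        paths["term_map"], sep="\t", index=False)
    (dataset.term_map[["term_id", "term_name"]].drop_duplicates()
     .to_csv(paths["term_names"], sep="\t", index=False))
    dataset.ct.to_csv(paths["qpcr_ct"], sep="\t", index=False,
                      float_format="%.6f")
    dataset.truth.to_json(paths["truth"])
    (out / "config.json").write_text(
        json.dumps(asdict(dataset.config), indent=1, sort_keys=True,
                   default=list) + "\n")
    paths["config"] = out / "config.json"
    return {k: str(v) for k, v in paths.items()}
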