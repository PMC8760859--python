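"""End-to-end orchestration: simulate -> normalize -> DE (four contrasts) ->
classify -> ceRNA -> hub ranking -> enrichment -> qPCR, with a JSON manifest
of output hashes and per-stage counts.

The four default contrasts are the study design's comparisons: injured vs
normal within each tissue, and ACL vs MCL within each condition. All outputs
are plain text and deterministic for a fixed config and seed, so two runs
produce byte-identical manifests.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, asdict
from pathlib import Path

import networkx as nx
import pandas as pd

from . import __version__
from .annotation import read_gtf
from .cerna import CeRNAModel, CeRNAThresholds
from .classify import classify_all, class_proportions
from .diffexpr import Contrast, NegativeBinomialDE
from .enrich import enrichment_test, read_term_map, top_terms
from .hubrank import (as_simple_graph, degree_scores, hub_table, mcc_scores,
                      top_k)
from .normalize import CountMatrix, fpkm, normalized_counts, size_factors
from .qpcr import DeltaDeltaCtModel
from .simulate import DEFAULT_CONTRASTS

__all__ = ["PipelineConfig", "run_all"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    counts: str
    design: str
    annotation: str
    interactions: str
    term_map: str
    outdir: str
    ppi: str | None = None
    term_names: str | None = None
    qpcr_ct: str | None = None
    contrasts: tuple[str, ...] = DEFAULT_CONTRASTS
    fc_min: float = 2.0
    fdr_max: float = 0.01
    shared_min: int = 5
    p_max: float = 0.01
    cerna_fdr_max: float = 0.01
    r_min: float = 0.7
    r_p_max: float = 0.05
    top_k_ppi: int = 30
    top_k_cerna: int = 50
    top_terms: int = 20
    qpcr_reference: str = "ACTB"
    qpcr_control: str = "control"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fdr_max", "p_max", "cerna_fdr_max", "r_p_max"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.fc_min < 1:
            raise ValueError("fc_min must be >= 1")
        if not -1 <= self.r_min <= 1:
            raise ValueError("r_min must lie in [-1, 1]")
        for name in ("shared_min", "top_k_ppi", "top_k_cerna", "top_terms"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        obj = json.loads(Path(path).read_text())
        if "contrasts" in obj:
            obj["contrasts"] = tuple(obj["contrasts"])
        return cls(**obj)

    def input_paths(self) -> dict[str, str]:
        paths = {"counts": self.counts, "design": self.design,
                 "annotation": self.annotation,
                 "interactions": self.interactions, "term_map": self.term_map}
        for opt in ("ppi", "term_names", "qpcr_ct"):
            if getattr(self, opt) is not None:
                paths[opt] = getattr(self, opt)
        return paths


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _slug(contrast_name: str) -> str:
    return contrast_name.replace("=", "-").replace(":", "__")


def _write_network(g: nx.Graph, base: Path) -> list[Path]:
    nx.write_graphml(g, base.with_suffix(".graphml"))
    nodes = pd.DataFrame(
        [(n, d.get("node_type", ""), d.get("regulation", ""))
         for n, d in sorted(g.nodes(data=True))],
        columns=["node_id", "node_type", "regulation"])
    edges = pd.DataFrame(
        [(u, v, d.get("edge_type", "")) for u, v, d in
         sorted(g.edges(data=True), key=lambda e: (e[0], e[1]))],
        columns=["source", "target", "edge_type"])
    nodes.to_csv(base.parent / (base.name + "_nodes.tsv"), sep="\t", index=False)
    edges.to_csv(base.parent / (base.name + "_edges.tsv"), sep="\t", index=False)
    return [base.with_suffix(".graphml"),
            base.parent / (base.name + "_nodes.tsv"),
            base.parent / (base.name + "_edges.tsv")]


def run_all(config: PipelineConfig) -> dict:
    """Execute every stage; returns (and writes) the run manifest."""
    missing = [f"{k}: {v}" for k, v in config.input_paths().items()
               if not Path(v).exists()]
    if missing:
        raise FileNotFoundError("missing pipeline inputs: " + "; ".join(missing))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    manifest: dict = {"cernet_version": __version__, "seed": config.seed,
                      "config": asdict(config), "stages": {}}
    outputs: list[Path] = []

    def stage(name):
        t0 = time.perf_counter()
        logger.info("stage %s: start", name)
        manifest["stages"][name] = {}
        return t0

    def done(name, t0, **counts):
        manifest["stages"][name].update(counts)
        logger.info("stage %s: done in %.2fs", name, time.perf_counter() - t0)

    # ---- normalize ----
    t0 = stage("normalize")
    counts = CountMatrix.from_tsv(config.counts)
    design = pd.read_csv(config.design, sep="\t", index_col="sample_id")
    sf = size_factors(counts)
    norm = normalized_counts(counts, sf)
    fp = fpkm(counts.subset_types("mRNA", "lncRNA"))
    ndir = outdir / "normalize"
    ndir.mkdir(exist_ok=True)
    sf.to_csv(ndir / "size_factors.tsv", sep="\t", float_format="%.6g")
    with open(ndir / "normalized_counts.tsv", "w") as fh:
        fh.write("# unit: normalized_count (raw / median-of-ratios size factor)\n")
        norm.to_csv(fh, sep="\t", index_label="feature_id", float_format="%.6g")
    with open(ndir / "fpkm.tsv", "w") as fh:
        fh.write("# unit: FPKM\n")
        fp.to_csv(fh, sep="\t", index_label="feature_id", float_format="%.6g")
    outputs += [ndir / "size_factors.tsv", ndir / "normalized_counts.tsv",
                ndir / "fpkm.tsv"]
    done("normalize", t0, n_features=len(counts.counts),
         n_samples=len(counts.samples))

    # ---- differential expression ----
    t0 = stage("de")
    model = NegativeBinomialDE(counts, design)
    dedir = outdir / "de"
    dedir.mkdir(exist_ok=True)
    de_results = {}
    de_counts = {}
    for cname in config.contrasts:
        res = model.fit(Contrast.parse(cname), fc_min=config.fc_min,
                        fdr_max=config.fdr_max)
        de_results[cname] = res
        path = dedir / f"{_slug(cname)}.tsv"
        res.to_tsv(path)
        outputs.append(path)
        ft = res.frame["feature_type"]
        sig = res.frame["call"] != "ns"
        de_counts[cname] = {
            "n_up": res.n_up, "n_down": res.n_down,
            "n_de_mrna": int((sig & (ft == "mRNA")).sum()),
            "n_de_lncrna": int((sig & (ft == "lncRNA")).sum()),
        }
    done("de", t0, contrasts=de_counts)

    # ---- lncRNA classification ----
    t0 = stage("classify")
    ann = read_gtf(config.annotation)
    results = classify_all(ann.lncrnas, ann.genes)
    cdir = outdir / "classify"
    cdir.mkdir(exist_ok=True)
    pd.DataFrame([(r.transcript_id, r.lncrna_class, r.evidence)
                  for r in results],
                 columns=["transcript_id", "class", "evidence"]).to_csv(
        cdir / "lncrna_classes.tsv", sep="\t", index=False)
    props = class_proportions(results) if results else {}
    (cdir / "class_proportions.json").write_text(
        json.dumps(props, indent=1, sort_keys=True) + "\n")
    outputs += [cdir / "lncrna_classes.tsv", cdir / "class_proportions.json"]
    done("classify", t0, n_lncrnas=len(results),
         proportions={k: round(v, 6) for k, v in props.items()})

    # ---- ceRNA ----
    t0 = stage("cerna")
    interactions = pd.read_csv(config.interactions, sep="\t")
    thresholds = CeRNAThresholds(shared_min=config.shared_min,
                                 p_max=config.p_max,
                                 fdr_max=config.cerna_fdr_max,
                                 r_min=config.r_min, r_p_max=config.r_p_max)
    cerna_res = CeRNAModel(interactions, norm, thresholds).fit()
    xdir = outdir / "cerna"
    xdir.mkdir(exist_ok=True)
    cerna_res.to_tsv(xdir / "pairs.tsv")
    outputs.append(xdir / "pairs.tsv")
    networks = {}
    net_counts = {}
    for cname in config.contrasts:
        net = cerna_res.differential_network(de_results[cname].de_status())
        networks[cname] = net
        outputs += _write_network(net, xdir / f"{_slug(cname)}_network")
        net_counts[cname] = {"n_nodes": net.number_of_nodes(),
                             "n_edges": net.number_of_edges()}
    done("cerna", t0, n_pairs_scored=len(cerna_res.pairs),
         n_pairs_passed=len(cerna_res.passed_pairs), networks=net_counts)

    # ---- hub ranking ----
    t0 = stage("hub")
    hdir = outdir / "hub"
    hdir.mkdir(exist_ok=True)
    hub_counts = {}
    ppi_graph = None
    if config.ppi is not None:
        ppi_df = pd.read_csv(config.ppi, sep="\t")
        ppi_graph = as_simple_graph(
            ppi_df.iloc[:, :2].astype(str).itertuples(index=False, name=None))
    for cname in config.contrasts:
        slug = _slug(cname)
        net = networks[cname]
        table = hub_table(net)
        table.to_csv(hdir / f"{slug}_cerna_hubs.tsv", sep="\t", index=False)
        outputs.append(hdir / f"{slug}_cerna_hubs.tsv")
        top_cerna = top_k(degree_scores(net), config.top_k_cerna) if len(net) else []
        pd.Series(top_cerna, name="node_id").to_csv(
            hdir / f"{slug}_cerna_top{config.top_k_cerna}.tsv", sep="\t",
            index=False)
        outputs.append(hdir / f"{slug}_cerna_top{config.top_k_cerna}.tsv")
        hub_counts[cname] = {"cerna_top_n": len(top_cerna)}
        if ppi_graph is not None:
            degs = [f for f, call in de_results[cname].de_status().items()
                    if call != "ns"
                    and counts.feature_type.get(f) == "mRNA"]
            sub = ppi_graph.subgraph(degs).copy()
            tb = hub_table(sub)
            tb.to_csv(hdir / f"{slug}_ppi_hubs.tsv", sep="\t", index=False)
            top_ppi = top_k(mcc_scores(sub), config.top_k_ppi) if len(sub) else []
            pd.Series(top_ppi, name="node_id").to_csv(
                hdir / f"{slug}_ppi_top{config.top_k_ppi}.tsv", sep="\t",
                index=False)
            outputs += [hdir / f"{slug}_ppi_hubs.tsv",
                        hdir / f"{slug}_ppi_top{config.top_k_ppi}.tsv"]
            hub_counts[cname]["ppi_top_n"] = len(top_ppi)
    done("hub", t0, contrasts=hub_counts)

    # ---- enrichment ----
    t0 = stage("enrich")
    term_map = read_term_map(config.term_map, config.term_names)
    edir = outdir / "enrich"
    edir.mkdir(exist_ok=True)
    universe = set(counts.counts.index[counts.feature_type == "mRNA"])
    enrich_counts = {}
    for cname in config.contrasts:
        slug = _slug(cname)
        query = {f for f, call in de_results[cname].de_status().items()
                 if call != "ns"} & universe
        if not query:
            enrich_counts[cname] = {"n_query": 0, "n_terms_tested": 0}
            continue
        res = enrichment_test(query, term_map, universe)
        res.to_csv(edir / f"{slug}_enrichment.tsv", sep="\t", index=False,
                   float_format="%.6g")
        tops = pd.concat([top_terms(res, config.top_terms, ns)
                          for ns in sorted(res["namespace"].unique())],
                         ignore_index=True)
        tops.to_csv(edir / f"{slug}_top{config.top_terms}.tsv", sep="\t",
                    index=False, float_format="%.6g")
        outputs += [edir / f"{slug}_enrichment.tsv",
                    edir / f"{slug}_top{config.top_terms}.tsv"]
        enrich_counts[cname] = {"n_query": len(query),
                                "n_terms_tested": len(res)}
    done("enrich", t0, contrasts=enrich_counts)

    # ---- qPCR ----
    if config.qpcr_ct is not None:
        t0 = stage("qpcr")
        qres = DeltaDeltaCtModel.from_tsv(config.qpcr_ct,
                                          config.qpcr_reference,
                                          config.qpcr_control).fit()
        qdir = outdir / "qpcr"
        qdir.mkdir(exist_ok=True)
        qres.to_tsv(qdir / "relative_expression.tsv")
        qres.gene_summary().to_csv(qdir / "gene_summary.tsv", sep="\t",
                                   index=False, float_format="%.6g")
        outputs += [qdir / "relative_expression.tsv", qdir / "gene_summary.tsv"]
        done("qpcr", t0,
             n_genes=int(qres.relative_expression["gene_id"].nunique()))

    manifest["files"] = {str(p.relative_to(outdir)): _sha256(p)
                         for p in sorted(set(outputs))}
    text = json.dumps(manifest, indent=1, sort_keys=True, default=str)
    (outdir / "manifest.json").write_text(text + "\n")
    return manifest
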