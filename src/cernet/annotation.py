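"""Gene and transcript models with GTF input/output.

Coordinates are stored 1-based inclusive (GTF convention) on the public
surface; interval arithmetic in :mod:`cernet.classify` converts to 0-based
half-open internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "GeneModel",
    "TranscriptModel",
    "GenomeAnnotation",
    "read_gtf",
    "write_gtf",
]

LNCRNA_CLASSES = ("lincRNA", "antisense", "intronic", "sense")


def _validate_span(name: str, start: int, end: int,
                   exons: Sequence[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    if start < 1 or end < start:
        raise ValueError(f"{name}: invalid span [{start}, {end}]")
    exons = tuple((int(s), int(e)) for s, e in exons)
    if not exons:
        raise ValueError(f"{name}: at least one exon required")
    prev_end = 0
    for s, e in exons:
        if s > e:
            raise ValueError(f"{name}: invalid exon [{s}, {e}]")
        if s < start or e > end:
            raise ValueError(f"{name}: exon [{s}, {e}] outside span")
        if s <= prev_end:
            raise ValueError(f"{name}: exons overlap or are unsorted")
        prev_end = e
    return exons


@dataclass(frozen=True)
class GeneModel:
    """A protein-coding gene: span plus sorted, non-overlapping exons."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        object.__setattr__(
            self, "exons",
            _validate_span(self.gene_id, self.start, self.end, self.exons))

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Gaps between consecutive exons, 1-based inclusive."""
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 > e1 + 1:
                out.append((e1 + 1, s2 - 1))
        return tuple(out)

    @property
    def length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)


@dataclass(frozen=True)
class TranscriptModel:
    """An lncRNA transcript; ``true_class`` is set by the simulator."""

    transcript_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...]
    true_class: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.transcript_id}: strand must be '+' or '-'")
        if self.true_class is not None and self.true_class not in LNCRNA_CLASSES:
            raise ValueError(f"{self.transcript_id}: unknown class {self.true_class!r}")
        object.__setattr__(
            self, "exons",
            _validate_span(self.transcript_id, self.start, self.end, self.exons))

    @property
    def length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)


@dataclass
class GenomeAnnotation:
    genes: list[GeneModel] = field(default_factory=list)
    lncrnas: list[TranscriptModel] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [g.gene_id for g in self.genes] + [t.transcript_id for t in self.lncrnas]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate feature ids in annotation")


def _attrs(**kv: str) -> str:
    return " ".join(f'{k} "{v}";' for k, v in kv.items())


def write_gtf(annotation: GenomeAnnotation, path: str | Path) -> None:
    """Write genes and lncRNA transcripts as a flat GTF.

    Attributes carried: gene_id, transcript_id, feature_type and (for
    lncRNAs) true_class when known. Output is deterministic: features in
    list order, exons in coordinate order.
    """
    lines = []
    for g in annotation.genes:
        base = _attrs(gene_id=g.gene_id, transcript_id=g.gene_id, feature_type="mRNA")
        lines.append(f"{g.chrom}\tcernet\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{base}")
        for s, e in g.exons:
            lines.append(f"{g.chrom}\tcernet\texon\t{s}\t{e}\t.\t{g.strand}\t.\t{base}")
    for t in annotation.lncrnas:
        kv = {"gene_id": t.transcript_id, "transcript_id": t.transcript_id,
              "feature_type": "lncRNA"}
        if t.true_class is not None:
            kv["true_class"] = t.true_class
        base = _attrs(**kv)
        lines.append(f"{t.chrom}\tcernet\ttranscript\t{t.start}\t{t.end}\t.\t{t.strand}\t.\t{base}")
        for s, e in t.exons:
            lines.append(f"{t.chrom}\tcernet\texon\t{s}\t{e}\t.\t{t.strand}\t.\t{base}")
    Path(path).write_text("\n".join(lines) + "\n")


def _parse_attrs(text: str) -> dict[str, str]:
    out = {}
    for chunk in text.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, val = chunk.partition(" ")
        out[key] = val.strip().strip('"')
    return out


def read_gtf(path: str | Path) -> GenomeAnnotation:
    """Read a GTF written by :func:`write_gtf` back into gene/transcript models."""
    records: dict[str, dict] = {}
    order: list[str] = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise ValueError(f"malformed GTF line: {line!r}")
        chrom, _, feature, start, end, _, strand, _, attrs = fields
        a = _parse_attrs(attrs)
        fid = a.get("transcript_id") or a.get("gene_id")
        if fid is None:
            raise ValueError(f"GTF line without gene_id/transcript_id: {line!r}")
        rec = records.get(fid)
        if rec is None:
            rec = records[fid] = {
                "chrom": chrom, "strand": strand,
                "feature_type": a.get("feature_type", "mRNA"),
                "true_class": a.get("true_class"),
                "span": None, "exons": [],
            }
            order.append(fid)
        if feature in ("gene", "transcript"):
            rec["span"] = (int(start), int(end))
        elif feature == "exon":
            rec["exons"].append((int(start), int(end)))
    genes, lncrnas = [], []
    for fid in order:
        rec = records[fid]
        exons = sorted(rec["exons"])
        span = rec["span"] or (exons[0][0], exons[-1][1])
        if rec["feature_type"] == "lncRNA":
            lncrnas.append(TranscriptModel(fid, rec["chrom"], rec["strand"],
                                           span[0], span[1], tuple(exons),
                                           rec["true_class"]))
        else:
            genes.append(GeneModel(fid, rec["chrom"], rec["strand"],
                                   span[0], span[1], tuple(exons)))
    return GenomeAnnotation(genes=genes, lncrnas=lncrnas)


def feature_lengths(annotation: GenomeAnnotation) -> dict[str, int]:
    """Exonic length per feature id (mRNAs and lncRNAs)."""
    out: dict[str, int] = {}
    for g in annotation.genes:
        out[g.gene_id] = g.length
    for t in annotation.lncrnas:
        out[t.transcript_id] = t.length
    return out


def iter_features(annotation: GenomeAnnotation) -> Iterable[tuple[str, str]]:
    for g in annotation.genes:
        yield g.gene_id, "mRNA"
    for t in annotation.lncrnas:
        yield t.transcript_id, "lncRNA"
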