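"""Positional classification of lncRNA transcripts against gene models.

Four classes, assigned by precedence (first match wins):

1. **lincRNA** — no base overlap with any gene span (intergenic);
2. **intronic** — contained entirely within a single intron of a gene,
   regardless of strand;
3. **antisense** — overlaps at least one exonic base of a gene on the
   opposite strand;
4. **sense** — overlaps at least one exonic base on the same strand.

A transcript that overlaps a gene span but matches none of the rules (for
example it covers only intronic bases while extending past the gene end) is
classified ``sense`` and logged, so every transcript receives exactly one
label. Containment is checked before exonic overlap because it is the more
specific relation; both orderings are defensible, this one is fixed here for
reproducibility.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

from .annotation import GeneModel, TranscriptModel

__all__ = ["ClassificationResult", "classify_lncrna", "classify_all",
           "class_proportions"]

logger = logging.getLogger(__name__)

CLASS_ORDER = ("lincRNA", "antisense", "intronic", "sense")


@dataclass(frozen=True)
class ClassificationResult:
    transcript_id: str
    lncrna_class: str
    evidence: str  # overlapping gene id, or "none" for lincRNA

    def __post_init__(self) -> None:
        if (self.evidence == "none") != (self.lncrna_class == "lincRNA"):
            raise ValueError("evidence='none' iff class='lincRNA'")


def _overlaps(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    # 1-based inclusive spans; convert to half-open for the comparison
    return a_start <= b_end and b_start <= a_end


def _within(inner: tuple[int, int], outer: tuple[int, int]) -> bool:
    return outer[0] <= inner[0] and inner[1] <= outer[1]


def classify_lncrna(transcript: TranscriptModel,
                    genes: Sequence[GeneModel]) -> ClassificationResult:
    """Assign one positional class to ``transcript`` relative to ``genes``."""
    hits = [g for g in genes
            if g.chrom == transcript.chrom
            and _overlaps(transcript.start, transcript.end, g.start, g.end)]
    if not hits:
        return ClassificationResult(transcript.transcript_id, "lincRNA", "none")
    for g in hits:
        for intron in g.introns:
            if _within((transcript.start, transcript.end), intron):
                return ClassificationResult(transcript.transcript_id, "intronic",
                                            g.gene_id)
    for g in hits:
        if g.strand != transcript.strand and any(
                _overlaps(transcript.start, transcript.end, s, e)
                for s, e in g.exons):
            return ClassificationResult(transcript.transcript_id, "antisense",
                                        g.gene_id)
    for g in hits:
        if g.strand == transcript.strand and any(
                _overlaps(transcript.start, transcript.end, s, e)
                for s, e in g.exons):
            return ClassificationResult(transcript.transcript_id, "sense",
                                        g.gene_id)
    # Overlaps a gene span but neither intron-contained nor exon-overlapping
    # (e.g. runs off the gene end through an intron): fall back to sense.
    logger.warning("transcript %s overlaps %s but matches no rule; "
                   "classified sense", transcript.transcript_id,
                   hits[0].gene_id)
    return ClassificationResult(transcript.transcript_id, "sense",
                                hits[0].gene_id)


def classify_all(lncrnas: Sequence[TranscriptModel],
                 genes: Sequence[GeneModel]) -> list[ClassificationResult]:
    return [classify_lncrna(t, genes) for t in lncrnas]


def class_proportions(
        results: Sequence[ClassificationResult | Mapping | str]
) -> dict[str, float]:
    """Fraction of transcripts per class, in CLASS_ORDER; sums to 1."""
    if len(results) == 0:
        raise ValueError("class_proportions requires at least one result")
    labels = []
    for r in results:
        if isinstance(r, ClassificationResult):
            labels.append(r.lncrna_class)
        elif isinstance(r, str):
            labels.append(r)
        else:
            labels.append(r["lncrna_class"])
    n = len(labels)
    return {c: labels.count(c) / n for c in CLASS_ORDER}
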