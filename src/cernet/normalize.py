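"""Library-size normalization and FPKM.

Size factors use the median-of-ratios estimator: each sample's factor is the
median, over features with all-positive counts, of that sample's count
divided by the feature's geometric mean across samples. Factors are rescaled
to geometric mean 1 so normalized counts stay on the raw-count scale.
FPKM_ij = c_ij * 1e9 / (length_i * total_j).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["CountMatrix", "size_factors", "normalized_counts", "fpkm"]

FEATURE_TYPES = ("mRNA", "lncRNA", "miRNA")


@dataclass
class CountMatrix:
    """Raw read counts (features x samples) with per-feature metadata.

    ``counts`` is a DataFrame indexed by feature id; ``feature_type`` and
    ``lengths`` are Series aligned to the same index.
    """

    counts: pd.DataFrame
    feature_type: pd.Series
    lengths: pd.Series

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate feature ids")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.allclose(vals, np.round(vals)):
            raise ValueError("counts must be integral")
        self.feature_type = self.feature_type.reindex(self.counts.index)
        self.lengths = self.lengths.reindex(self.counts.index)
        if self.feature_type.isna().any() or self.lengths.isna().any():
            raise ValueError("feature_type/lengths must cover every feature")
        if (self.lengths < 1).any():
            raise ValueError("feature lengths must be >= 1")
        bad = set(self.feature_type) - set(FEATURE_TYPES)
        if bad:
            raise ValueError(f"unknown feature types: {sorted(bad)}")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def subset_types(self, *types: str) -> "CountMatrix":
        keep = self.feature_type.isin(types)
        return CountMatrix(self.counts.loc[keep],
                           self.feature_type.loc[keep],
                           self.lengths.loc[keep])

    def to_tsv(self, path: str | Path) -> None:
        out = pd.DataFrame({"feature_type": self.feature_type,
                            "length": self.lengths})
        out = pd.concat([out, self.counts], axis=1)
        out.to_csv(path, sep="\t", index_label="feature_id")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col="feature_id")
        ftype = df.pop("feature_type")
        lengths = df.pop("length")
        return cls(df.astype(np.int64), ftype, lengths.astype(np.int64))


def size_factors(counts: CountMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    Raises if no feature has positive counts in every sample (the estimator
    has no reference); a pseudo-reference fallback is deliberately not
    applied silently.
    """
    mat = counts.counts if isinstance(counts, CountMatrix) else counts
    vals = mat.to_numpy(dtype=float)
    allpos = (vals > 0).all(axis=1)
    if not allpos.any():
        raise ValueError(
            "no feature has positive counts in all samples; median-of-ratios "
            "is undefined (consider filtering or a pseudo-reference upstream)")
    logv = np.log(vals[allpos])
    log_gm = logv.mean(axis=1, keepdims=True)
    log_sf = np.median(logv - log_gm, axis=0)
    log_sf = log_sf - log_sf.mean()  # geometric mean 1
    return pd.Series(np.exp(log_sf), index=mat.columns, name="size_factor")


def normalized_counts(counts: CountMatrix | pd.DataFrame,
                      factors: pd.Series | None = None) -> pd.DataFrame:
    """Raw counts divided by per-sample size factors."""
    mat = counts.counts if isinstance(counts, CountMatrix) else counts
    if factors is None:
        factors = size_factors(mat)
    return mat / factors


def fpkm(counts: CountMatrix) -> pd.DataFrame:
    """Fragments per kilobase of transcript per million mapped reads."""
    totals = counts.counts.sum(axis=0)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"samples with zero total counts: {bad}")
    lengths = counts.lengths.to_numpy(dtype=float)[:, None]
    return counts.counts * 1e9 / (lengths * totals.to_numpy(dtype=float))
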