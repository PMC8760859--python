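"""Negative-binomial differential expression with BH correction.

The test is a moment-matched NB Wald test on normalized counts: per-feature
dispersion is estimated by pooled method of moments and shrunk strongly
(weight 0.9) toward a mean–dispersion trend alpha(m) = a0 + a1/m fitted
across all features, and the log ratio of group means is compared to its
delta-method standard error on a standard normal reference — with thousands
of features the trended dispersion is effectively known, while per-feature
moment estimates at small n are too noisy to stand alone. This is
deliberately simpler
than a full GLM fit with empirical-Bayes shrinkage; the calling rule is the
conventional one for bulk RNA-seq screens: FDR < 0.01 and fold change
(max(FC, 1/FC)) >= 2, both strict on FDR.

Fold change is the ratio of group means, group 1 over group 2; groups whose
mean is zero receive a +0.5 continuity correction (applied to both means) so
FC and the test statistic are always finite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .normalize import CountMatrix, normalized_counts, size_factors

__all__ = ["Contrast", "bh_adjust", "nb_test", "call_de",
           "NegativeBinomialDE", "DEResults"]

_MIN_DISPERSION = 1e-8
_TREND_WEIGHT = 0.9  # weight of the fitted trend in the shrunk dispersion


@dataclass(frozen=True)
class Contrast:
    """A two-group comparison: ``factor`` at ``level1`` vs ``level2`` with
    every other factor fixed at the levels in ``fixed``."""

    factor: str
    level1: str
    level2: str
    fixed: tuple[tuple[str, str], ...] = field(default=())

    @classmethod
    def parse(cls, text: str) -> "Contrast":
        """Parse e.g. ``"tissue=ACL:condition=injured-vs-normal"``."""
        fixed = []
        tested = None
        for part in text.split(":"):
            key, _, val = part.partition("=")
            if not key or not val:
                raise ValueError(f"malformed contrast component {part!r}")
            if "-vs-" in val:
                if tested is not None:
                    raise ValueError(f"more than one tested factor in {text!r}")
                l1, _, l2 = val.partition("-vs-")
                tested = (key, l1, l2)
            else:
                fixed.append((key, val))
        if tested is None:
            raise ValueError(f"no '-vs-' component in contrast {text!r}")
        return cls(tested[0], tested[1], tested[2], tuple(fixed))

    @property
    def name(self) -> str:
        parts = [f"{k}={v}" for k, v in self.fixed]
        parts.append(f"{self.factor}={self.level1}-vs-{self.level2}")
        return ":".join(parts)

    def groups(self, design: pd.DataFrame) -> tuple[list[str], list[str]]:
        """Sample ids of (group1, group2) under ``design``
        (index = sample_id, columns = factors)."""
        mask = pd.Series(True, index=design.index)
        for key, val in self.fixed:
            mask &= design[key] == val
        g1 = list(design.index[mask & (design[self.factor] == self.level1)])
        g2 = list(design.index[mask & (design[self.factor] == self.level2)])
        if len(g1) < 2 or len(g2) < 2:
            raise ValueError(
                f"contrast {self.name}: need >=2 samples per group, "
                f"got {len(g1)} vs {len(g2)}")
        return g1, g2


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _estimate_dispersions(norm: pd.DataFrame, g1: list[str],
                          g2: list[str]) -> np.ndarray:
    """Pooled method-of-moments dispersion, shrunk toward an a0 + a1/m trend."""
    n1, n2 = len(g1), len(g2)
    m1 = norm[g1].mean(axis=1).to_numpy()
    m2 = norm[g2].mean(axis=1).to_numpy()
    v1 = norm[g1].var(axis=1, ddof=1).to_numpy()
    v2 = norm[g2].var(axis=1, ddof=1).to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        a1 = np.where(m1 > 0, (v1 - m1) / m1**2, 0.0)
        a2 = np.where(m2 > 0, (v2 - m2) / m2**2, 0.0)
    raw = ((n1 - 1) * a1 + (n2 - 1) * a2) / (n1 + n2 - 2)

    mbar = np.clip((m1 + m2) / 2, 0.5, None)
    # trend fitted on the unclipped moment estimates: clipping first would
    # bias the trend upward and make the test conservative
    if len(raw) >= 10:
        X = np.column_stack([np.ones(len(mbar)), 1.0 / mbar])
        coef, *_ = np.linalg.lstsq(X, raw, rcond=None)
        a0 = max(float(coef[0]), 0.0)
        aslope = max(float(coef[1]), 0.0)
        trend = a0 + aslope / mbar
    else:
        trend = np.full_like(raw, max(float(np.median(np.clip(raw, 0, None))),
                                      0.01))
    shrunk = _TREND_WEIGHT * trend + (1 - _TREND_WEIGHT) * np.clip(raw, 0.0, None)
    return np.clip(shrunk, _MIN_DISPERSION, None)


def nb_test(counts: CountMatrix, design: pd.DataFrame,
            contrast: Contrast) -> pd.DataFrame:
    """Per-feature Wald test of equal group means under an NB model.

    Returns a DataFrame (index = feature id) with base_mean_1, base_mean_2
    (normalized scale, continuity-corrected where a group mean is zero),
    dispersion, statistic and p_value in (0, 1].
    """
    g1, g2 = contrast.groups(design)
    missing = (set(g1) | set(g2)) - set(counts.samples)
    if missing:
        raise ValueError(f"design samples absent from counts: {sorted(missing)}")
    sub = counts.counts[g1 + g2]
    sf = size_factors(sub)
    norm = normalized_counts(sub, sf)

    alpha = _estimate_dispersions(norm, g1, g2)
    m1 = norm[g1].mean(axis=1).to_numpy()
    m2 = norm[g2].mean(axis=1).to_numpy()
    zero = (m1 <= 0) | (m2 <= 0)
    m1c = np.where(zero, m1 + 0.5, m1)
    m2c = np.where(zero, m2 + 0.5, m2)

    n1, n2 = len(g1), len(g2)
    se2 = (1.0 / m1c + alpha) / n1 + (1.0 / m2c + alpha) / n2
    z = (np.log(m1c) - np.log(m2c)) / np.sqrt(se2)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return pd.DataFrame({
        "base_mean_1": m1c, "base_mean_2": m2c,
        "dispersion": alpha, "statistic": z, "p_value": p,
    }, index=counts.counts.index)


def call_de(results: pd.DataFrame, fc_min: float = 2.0,
            fdr_max: float = 0.01) -> pd.DataFrame:
    """Add FC, log2FC, fdr and the up/down/ns call to a test table.

    up: FC >= fc_min and fdr < fdr_max; down: FC <= 1/fc_min and
    fdr < fdr_max; otherwise ns. The FDR comparison is strict.
    """
    out = results.copy()
    fc = out["base_mean_1"] / out["base_mean_2"]
    out["fc"] = fc
    out["log2fc"] = np.log2(fc)
    out["fdr"] = bh_adjust(out["p_value"].to_numpy())
    sig = out["fdr"] < fdr_max
    call = np.where(sig & (fc >= fc_min), "up",
                    np.where(sig & (fc <= 1.0 / fc_min), "down", "ns"))
    out["call"] = call
    return out


class DEResults:
    """Differential-expression results for one contrast."""

    def __init__(self, frame: pd.DataFrame, contrast: Contrast,
                 fc_min: float, fdr_max: float) -> None:
        self.frame = frame
        self.contrast = contrast
        self.fc_min = fc_min
        self.fdr_max = fdr_max

    @property
    def n_up(self) -> int:
        return int((self.frame["call"] == "up").sum())

    @property
    def n_down(self) -> int:
        return int((self.frame["call"] == "down").sum())

    def de_status(self) -> dict[str, str]:
        """feature id -> up/down/ns, for network extraction."""
        return dict(self.frame["call"])

    def summary(self) -> str:
        lines = [
            "Negative-binomial differential expression",
            f"  contrast:   {self.contrast.name}",
            f"  features:   {len(self.frame)}",
            f"  rule:       FDR < {self.fdr_max:g} and max(FC, 1/FC) >= {self.fc_min:g}",
            f"  up:         {self.n_up}",
            f"  down:       {self.n_down}",
            f"  ns:         {len(self.frame) - self.n_up - self.n_down}",
        ]
        return "\n".join(lines)

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index_label="feature_id",
                          float_format="%.6g")

    def plot_volcano(self, ax=None):
        """Volcano plot: log2FC vs -log10 FDR, calls colored."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        colors = {"up": "tab:red", "down": "tab:green", "ns": "0.6"}
        for call, grp in self.frame.groupby("call"):
            ax.scatter(grp["log2fc"], -np.log10(grp["fdr"]), s=6,
                       c=colors.get(call, "0.6"), label=call)
        ax.axhline(-np.log10(self.fdr_max), ls="--", lw=0.8, c="k")
        for x in (np.log2(self.fc_min), -np.log2(self.fc_min)):
            ax.axvline(x, ls="--", lw=0.8, c="k")
        ax.set_xlabel("log2 fold change")
        ax.set_ylabel("-log10 FDR")
        ax.legend(frameon=False)
        ax.set_title(self.contrast.name)
        return ax


class NegativeBinomialDE:
    """Model object: counts + design; ``fit`` runs one contrast."""

    def __init__(self, counts: CountMatrix, design: pd.DataFrame) -> None:
        missing = set(counts.samples) - set(design.index)
        if missing:
            raise ValueError(f"samples missing from design: {sorted(missing)}")
        self.counts = counts
        self.design = design

    @classmethod
    def from_tsv(cls, counts_path: str | Path,
                 design_path: str | Path) -> "NegativeBinomialDE":
        counts = CountMatrix.from_tsv(counts_path)
        design = pd.read_csv(design_path, sep="\t", index_col="sample_id")
        return cls(counts, design)

    def fit(self, contrast: Contrast | str, fc_min: float = 2.0,
            fdr_max: float = 0.01) -> DEResults:
        if isinstance(contrast, str):
            contrast = Contrast.parse(contrast)
        res = nb_test(self.counts, self.design, contrast)
        res = call_de(res, fc_min=fc_min, fdr_max=fdr_max)
        res.insert(0, "feature_type",
                   self.counts.feature_type.reindex(res.index))
        return DEResults(res, contrast, fc_min, fdr_max)
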