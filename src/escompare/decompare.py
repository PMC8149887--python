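"""Directional comparison of differential-expression evidence between two
gene sets.

The core statistic of the pipeline: within each fold-change direction,
the -log10 p-value distributions of the two set-specific gene blocks are
compared by a two-sided Wilcoxon rank-sum test, effect size is reported as
Cohen's d with the pooled standard deviation (the two groups have unequal
sizes), and the observed test is calibrated against a size-matched
permutation null drawn from the nonessential gene pool.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import DETable, GeneSet

logger = logging.getLogger("escompare")

#: sample-size bound under which the exact rank-sum null is used (no ties)
EXACT_MAX_N = 20


@dataclass
class DirectionalSlice:
    """Genes of one fold-change direction with their -log10(p) scores.

    Genes with zero fold change or a missing p-value are excluded upstream;
    p is floored before the transform so scores are finite.
    """

    direction: str                # "up" | "down"
    scores: pd.Series             # -log10 p, indexed by gene id

    def __len__(self) -> int:
        return len(self.scores)


def split_by_direction(table: DETable, p_column: str = "raw",
                       neglog10_floor: float = 1e-300
                       ) -> tuple[DirectionalSlice, DirectionalSlice]:
    """Split a DE table into up- and downregulated slices by the sign of the
    log2 fold change and attach -log10 p scores.

    Returns ``(up, down)``. Genes with log2FC == 0 or missing p are excluded
    and counted in the log. Raises if both slices come out empty.
    """
    if len(table) == 0:
        raise ValueError("empty DE table")
    df = table.data
    pcol = "pvalue" if p_column == "raw" else "padj"
    missing_p = df[pcol].isna()
    zero_fc = df["log2fc"].isna() | (df["log2fc"] == 0)
    keep = ~(missing_p | zero_fc)
    n_missing, n_zero = int(missing_p.sum()), int((zero_fc & ~missing_p).sum())
    if n_missing or n_zero:
        logger.info("split_by_direction: excluded %d missing-p and %d zero-FC genes",
                    n_missing, n_zero)
    sub = df[keep]
    score = -np.log10(np.maximum(sub[pcol].to_numpy(float), neglog10_floor))
    scores = pd.Series(score, index=sub["gene"].to_numpy())
    up_mask = sub["log2fc"].to_numpy() > 0
    up = DirectionalSlice("up", scores[up_mask])
    down = DirectionalSlice("down", scores[~up_mask])
    if len(up) == 0 and len(down) == 0:
        raise ValueError("both directional slices are empty after exclusions")
    return up, down


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    Returns ``(W, p)`` where W is the rank sum of *x* in the combined sample.
    The exact null distribution is used when n_x + n_y <= 20 and there are
    no ties (two-sided p = min(1, 2 * min(lower tail, upper tail)), tails
    inclusive); otherwise the normal approximation with tie and continuity
    corrections. If every value in both samples is identical the test is
    uninformative and p = 1 is returned with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 1 or len(y) < 1:
        raise ValueError("both samples must have size >= 1")
    combined = np.concatenate([x, y])
    w_stat = float(stats.rankdata(combined)[: len(x)].sum())
    if np.all(combined == combined[0]):
        warnings.warn("wilcoxon_rank_sum: all values identical; p = 1")
        return w_stat, 1.0
    has_ties = len(np.unique(combined)) < len(combined)
    if len(combined) <= EXACT_MAX_N and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    p = float(min(res.pvalue, 1.0))
    if p <= 0.0:  # numerically underflowed two-sided p
        p = float(np.nextafter(0.0, 1.0))
    return w_stat, p


@dataclass
class ComparisonResult:
    """Full summary of one directional two-set comparison: group sizes,
    means and SDs of the -log10 p scores, pooled SD, Cohen's d, and the
    Wilcoxon rank-sum statistic with its two-sided p.

    d > 0 means the Y group (first argument) carries stronger DE evidence.
    """

    direction: str
    n_y: int
    n_x: int
    mean_y: float
    mean_x: float
    sd_y: float
    sd_x: float
    pooled_sd: float
    d: float | None
    w_stat: float | None = None
    p_wilcoxon: float | None = None

    def as_dict(self) -> dict:
        return {
            "direction": self.direction, "n_y": self.n_y, "n_x": self.n_x,
            "mean_y": self.mean_y, "mean_x": self.mean_x,
            "sd_y": self.sd_y, "sd_x": self.sd_x, "pooled_sd": self.pooled_sd,
            "cohens_d": self.d, "w_stat": self.w_stat,
            "p_wilcoxon": self.p_wilcoxon,
        }


def cohens_d_pooled(y, x, direction: str = "") -> ComparisonResult:
    """Cohen's d with the pooled standard deviation:

        d = (mean(Y) - mean(X)) / s,
        s = sqrt(((n_X - 1) s_X^2 + (n_Y - 1) s_Y^2) / (n_X + n_Y - 2))

    with sample (n-1) variances. If the pooled SD is zero, d is undefined
    and reported as None with a warning.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    n_y, n_x = len(y), len(x)
    if n_y < 2 or n_x < 2:
        raise ValueError("both samples must have size >= 2 for a pooled SD")
    sd_y = float(np.std(y, ddof=1))
    sd_x = float(np.std(x, ddof=1))
    pooled = float(np.sqrt(((n_x - 1) * sd_x**2 + (n_y - 1) * sd_y**2)
                           / (n_x + n_y - 2)))
    if pooled == 0.0:
        warnings.warn("cohens_d_pooled: zero pooled SD; d undefined")
        d = None
    else:
        d = float((y.mean() - x.mean()) / pooled)
    return ComparisonResult(direction=direction, n_y=n_y, n_x=n_x,
                            mean_y=float(y.mean()), mean_x=float(x.mean()),
                            sd_y=sd_y, sd_x=sd_x, pooled_sd=pooled, d=d)


def compare_gene_sets(dslice: DirectionalSlice, set_y: GeneSet,
                      set_x: GeneSet) -> ComparisonResult:
    """Compare the -log10 p scores of two gene sets within one directional
    slice (Wilcoxon two-sided + pooled-SD Cohen's d).

    Genes belonging to both sets (the shared block) are excluded from both
    samples; the intended inputs are the set-specific blocks of a
    :class:`~escompare.geneset.Partition`.
    """
    shared = set_y.as_set() & set_x.as_set()
    idx = dslice.scores.index
    y_mask = idx.isin(set_y.as_set() - shared)
    x_mask = idx.isin(set_x.as_set() - shared)
    y = dslice.scores[y_mask].to_numpy()
    x = dslice.scores[x_mask].to_numpy()
    for label, arr, gs in (("Y", y, set_y), ("X", x, set_x)):
        if len(arr) < 2:
            raise ValueError(
                f"set {label} ({gs.name}) has only {len(arr)} genes in the "
                f"{dslice.direction} slice; need >= 2"
            )
    result = cohens_d_pooled(y, x, direction=dslice.direction)
    result.w_stat, result.p_wilcoxon = wilcoxon_rank_sum(y, x)
    return result


@dataclass
class PermutationResult:
    """Size-matched permutation null for one directional comparison.

    Each permutation draws two disjoint gene sets of the observed sizes
    from the nonessential pool and repeats the Wilcoxon comparison;
    ``empirical_quantile`` is the fraction of null p-values at or below the
    observed one.
    """

    null_pvalues: np.ndarray
    observed_p: float
    seed: int

    @property
    def empirical_quantile(self) -> float:
        return float(np.mean(self.null_pvalues <= self.observed_p))


def permutation_null(dslice: DirectionalSlice, pool: GeneSet, size_y: int,
                     size_x: int, n_perm: int, seed: int,
                     observed_p: float = 1.0) -> PermutationResult:
    """Build the size-matched null by repeatedly sampling, without
    replacement and disjointly within each iteration, ``size_y`` and
    ``size_x`` genes from *pool* (genes in the slice belonging to neither
    essential set) and running the two-sided Wilcoxon comparison.
    """
    pool_scores = dslice.scores[dslice.scores.index.isin(pool.as_set())].to_numpy()
    n_pool = len(pool_scores)
    need = size_y + size_x
    if n_pool < need:
        raise ValueError(f"permutation pool too small: need {need} genes "
                         f"({size_y}+{size_x}), have {n_pool}")
    rng = np.random.default_rng(seed)
    null_p = np.empty(n_perm)
    for i in range(n_perm):
        draw = rng.choice(n_pool, size=need, replace=False)
        y = pool_scores[draw[:size_y]]
        x = pool_scores[draw[size_y:]]
        _, null_p[i] = wilcoxon_rank_sum(y, x)
    return PermutationResult(null_pvalues=null_p, observed_p=observed_p, seed=seed)
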