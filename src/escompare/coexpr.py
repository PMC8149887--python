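"""Signed co-expression network construction, module detection, eigengenes
and temporal-pattern classification for developmental expression data.

The network follows the weighted co-expression construction: a signed
adjacency ``a_ij = ((1 + cor_ij)/2)^beta`` (soft-thresholding power beta,
default 15), transformed into a topological overlap matrix (TOM), with
modules cut from an average-linkage dendrogram of the TOM dissimilarity
(1 - TOM). Module detection uses a static-height cut rather than the
dynamic tree-cut heuristic; see docs/methods.md for the rationale. Module
eigengenes are first principal components of the standardized module
submatrix; modules whose eigengenes correlate above a merge threshold
(default 0.9) are merged. Each eigengene trajectory over developmental
age is classified into one of three temporal patterns (prenatal rise then
sustained, low prenatal then intermediate, prenatal high then drop).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .io import ExpressionMatrix

logger = logging.getLogger("escompare")

UNASSIGNED = 0
#: default static cut height on the (1 - TOM) average-linkage dendrogram
DEFAULT_CUT_HEIGHT = 0.8
#: biweight midcorrelation tuning constant, in median absolute deviations
BICOR_C = 9.0

PATTERNS = ("prenatal_rise_sustained", "low_prenatal_mid",
            "prenatal_high_drop", "unclassified")


# ---------------------------------------------------------------------------
# Correlation and adjacency
# ---------------------------------------------------------------------------


def _biweight_midcorrelation(values: np.ndarray) -> np.ndarray:
    """Row-wise biweight midcorrelation matrix.

    Outlier-resistant correlation using Tukey biweights with tuning constant
    ``BICOR_C`` MADs. Rows with zero MAD fall back to ordinary standardized
    deviations (unit weights), matching common practice.
    """
    med = np.median(values, axis=1, keepdims=True)
    dev = values - med
    mad = np.median(np.abs(dev), axis=1, keepdims=True)
    zero_mad = (mad == 0).ravel()
    with np.errstate(divide="ignore", invalid="ignore"):
        u = dev / (BICOR_C * mad)
    w = (1 - u**2) ** 2
    w[np.abs(u) >= 1] = 0.0
    if zero_mad.any():
        w[zero_mad] = 1.0
        dev[zero_mad] = values[zero_mad] - values[zero_mad].mean(axis=1, keepdims=True)
    xt = dev * w
    norms = np.sqrt((xt**2).sum(axis=1, keepdims=True))
    xt = xt / norms
    return np.clip(xt @ xt.T, -1.0, 1.0)


def signed_adjacency(expr: ExpressionMatrix, beta: float = 15.0,
                     method: str = "pearson") -> pd.DataFrame:
    """Signed soft-thresholded adjacency ``a_ij = ((1 + cor_ij) / 2)^beta``.

    Correlation is Pearson by default or biweight midcorrelation
    (``method="biweight"``). Zero-variance genes are removed first. The
    result is symmetric, in [0, 1], with unit diagonal.
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    if expr.values.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    keep = ~expr.zero_variance
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("signed_adjacency: removed %d zero-variance genes", n_drop)
    values = expr.values.loc[keep].to_numpy(float)
    genes = expr.values.index[keep]
    if method == "pearson":
        cor = np.atleast_2d(np.corrcoef(values))
    elif method == "biweight":
        cor = _biweight_midcorrelation(values)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    adj = ((1.0 + cor) / 2.0) ** beta
    np.fill_diagonal(adj, 1.0)
    adj = (adj + adj.T) / 2.0
    return pd.DataFrame(adj, index=genes, columns=genes)


def topological_overlap(adjacency: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Topological overlap matrix of a symmetric adjacency in [0, 1]:

        omega_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij)

    with ``l_ij = sum_{u != i,j} a_iu a_uj`` (shared-neighbor weight) and
    ``k_i = sum_{u != i} a_iu`` (connectivity); the diagonal is set to 1.
    """
    is_frame = isinstance(adjacency, pd.DataFrame)
    a = adjacency.to_numpy(float) if is_frame else np.asarray(adjacency, float)
    if a.shape[0] != a.shape[1] or not np.allclose(a, a.T, atol=1e-12):
        raise ValueError("adjacency must be symmetric")
    if a.min() < -1e-12 or a.max() > 1 + 1e-12:
        raise ValueError("adjacency values must lie in [0, 1]")
    a0 = a.copy()
    np.fill_diagonal(a0, 0.0)
    k = a0.sum(axis=1)
    # l_ij over u != i,j: full product minus the u=i and u=j terms
    l_full = a0 @ a0
    l = l_full  # a0 has zero diagonal so u=i and u=j terms are already absent
    denom = np.minimum.outer(k, k) + 1.0 - a0
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = (l + a0) / denom
    tom[~np.isfinite(tom)] = 0.0
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    if is_frame:
        return pd.DataFrame(tom, index=adjacency.index, columns=adjacency.columns)
    return tom


# ---------------------------------------------------------------------------
# Module detection
# ---------------------------------------------------------------------------


@dataclass
class ModuleAssignment:
    """Gene -> module label mapping. Label 0 is reserved for unassigned
    genes; assigned labels are 1..K ordered by decreasing module size."""

    labels: pd.Series  # int, indexed by gene

    @property
    def module_ids(self) -> list[int]:
        ids = sorted(set(self.labels) - {UNASSIGNED})
        return ids

    @property
    def module_sizes(self) -> dict[int, int]:
        counts = self.labels[self.labels != UNASSIGNED].value_counts()
        return {int(k): int(v) for k, v in counts.items()}

    def members(self, module: int) -> pd.Index:
        return self.labels.index[self.labels == module]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"gene": self.labels.index, "module": self.labels.values})


def _relabel_by_size(labels: pd.Series) -> pd.Series:
    """Renumber assigned modules 1..K by decreasing size (ties: stable by
    old label)."""
    counts = labels[labels != UNASSIGNED].value_counts()
    order = sorted(counts.index, key=lambda m: (-counts[m], m))
    mapping = {old: new for new, old in enumerate(order, start=1)}
    mapping[UNASSIGNED] = UNASSIGNED
    return labels.map(mapping)


def detect_modules(tom: pd.DataFrame, min_module_size: int = 30,
                   cut_height: float = DEFAULT_CUT_HEIGHT) -> ModuleAssignment:
    """Cut modules from the TOM dissimilarity dendrogram.

    Average-linkage hierarchical clustering of (1 - TOM) with a static cut
    at ``cut_height``; clusters smaller than ``min_module_size`` become
    unassigned. Labels are ordered by decreasing module size.
    """
    genes = tom.index
    dissim = 1.0 - tom.to_numpy(float)
    np.fill_diagonal(dissim, 0.0)
    z = linkage(squareform(dissim, checks=False), method="average")
    raw = fcluster(z, t=cut_height, criterion="distance")
    labels = pd.Series(raw, index=genes)
    counts = labels.value_counts()
    small = counts.index[counts < min_module_size]
    labels[labels.isin(small)] = UNASSIGNED
    labels = _relabel_by_size(labels)
    if (labels == UNASSIGNED).all():
        logger.warning("detect_modules: no module reached min size %d", min_module_size)
    return ModuleAssignment(labels)


# ---------------------------------------------------------------------------
# Eigengenes
# ---------------------------------------------------------------------------


@dataclass
class Eigengene:
    """First principal component of a module's standardized expression.

    ``scores`` is a unit-norm per-sample vector, sign-oriented so that its
    correlation with the module's mean standardized profile is >= 0.
    """

    module: int
    scores: pd.Series            # unit norm, indexed by sample
    variance_explained: float


def module_eigengene(expr: ExpressionMatrix, assignment: ModuleAssignment,
                     module: int) -> Eigengene:
    members = assignment.members(module)
    if len(members) < 2:
        raise ValueError(f"module {module} has {len(members)} genes; need >= 2")
    sub = expr.values.loc[members].to_numpy(float)
    sd = sub.std(axis=1, ddof=1, keepdims=True)
    keep = sd.ravel() > 0
    sub = sub[keep]
    if sub.shape[0] == 0:
        raise ValueError(f"module {module}: all member genes are constant")
    z = (sub - sub.mean(axis=1, keepdims=True)) / sd[keep]
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    if s[0] == 0:
        raise ValueError(f"module {module}: degenerate (rank-0) submatrix")
    scores = vt[0]
    mean_profile = z.mean(axis=0)
    if np.dot(scores, mean_profile) < 0:
        scores = -scores
    var_explained = float(s[0] ** 2 / (s**2).sum())
    return Eigengene(module=module,
                     scores=pd.Series(scores, index=expr.samples),
                     variance_explained=var_explained)


def all_eigengenes(expr: ExpressionMatrix,
                   assignment: ModuleAssignment) -> dict[int, Eigengene]:
    return {m: module_eigengene(expr, assignment, m) for m in assignment.module_ids}


def merge_modules(expr: ExpressionMatrix, assignment: ModuleAssignment,
                  eigengenes: dict[int, Eigengene],
                  merge_threshold: float = 0.9
                  ) -> tuple[ModuleAssignment, dict[int, Eigengene]]:
    """Iteratively merge the module pair with the highest eigengene
    correlation above ``merge_threshold``, recomputing the merged module's
    eigengene, until no pair qualifies. Ties break toward the smaller label
    pair; the merged module keeps the smaller label. Labels are renumbered
    by decreasing size at the end.
    """
    labels = assignment.labels.copy()
    eg = dict(eigengenes)
    while True:
        ids = sorted(eg)
        best: tuple[float, int, int] | None = None
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                r = float(np.corrcoef(eg[a].scores, eg[b].scores)[0, 1])
                if r > merge_threshold and (best is None or r > best[0] + 1e-15):
                    best = (r, a, b)
        if best is None:
            break
        _, a, b = best
        labels[labels == b] = a
        del eg[b]
        eg[a] = module_eigengene(expr, ModuleAssignment(labels), a)
    labels = _relabel_by_size(labels)
    merged = ModuleAssignment(labels)
    return merged, all_eigengenes(expr, merged)


# ---------------------------------------------------------------------------
# Temporal patterns
# ---------------------------------------------------------------------------


def classify_temporal_pattern(eigengene: Eigengene, age_days: pd.Series,
                              prenatal: pd.Series, margin: float = 0.25) -> str:
    """Assign one of the three developmental trajectory patterns.

    The eigengene scores are standardized to unit SD across all samples,
    then averaged in three windows: the first and last thirds of the
    prenatal samples (by sample count, ages ascending) and all postnatal
    samples. With margin ``delta`` (default 0.25 SD):

    * prenatal rise (late - early > delta) that is sustained postnatally
      (postnatal >= late - delta) -> ``prenatal_rise_sustained``;
    * flat prenatal (|late - early| <= delta) with higher postnatal level
      (postnatal - late > delta) -> ``low_prenatal_mid``;
    * prenatal fall (early - late > delta) that stays down
      (postnatal <= late + delta) -> ``prenatal_high_drop``;
    * anything else -> ``unclassified``.
    """
    order = age_days.sort_values(kind="stable").index
    z = eigengene.scores[order].to_numpy(float)
    pre_mask = prenatal[order].to_numpy(bool)
    n_pre, n_post = int(pre_mask.sum()), int((~pre_mask).sum())
    if n_pre < 3 or n_post < 3:
        raise ValueError(f"need >= 3 prenatal and >= 3 postnatal samples, "
                         f"got {n_pre} and {n_post}")
    sd = z.std(ddof=1)
    if sd == 0:
        return "unclassified"
    z = (z - z.mean()) / sd
    pre = z[pre_mask]
    k = max(1, n_pre // 3)
    early = float(pre[:k].mean())
    late = float(pre[-k:].mean())
    post = float(z[~pre_mask].mean())
    rising = late - early > margin
    falling = early - late > margin
    if rising and post >= late - margin:
        return "prenatal_rise_sustained"
    if falling and post <= late + margin:
        return "prenatal_high_drop"
    if not rising and not falling and post - late > margin:
        return "low_prenatal_mid"
    return "unclassified"


def classify_all_patterns(eigengenes: dict[int, Eigengene], expr: ExpressionMatrix,
                          margin: float = 0.25) -> dict[int, str]:
    return {m: classify_temporal_pattern(eg, expr.age_days, expr.prenatal, margin)
            for m, eg in eigengenes.items()}
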