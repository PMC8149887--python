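"""Gene-set enrichment by Fisher's exact test with Benjamini-Hochberg
correction, and the Poisson de novo mutation expectation test.

Over-representation of a query gene set in each category (co-expression
module, risk-gene list, tissue panel) is tested on the 2x2 membership
table; p-values are corrected across categories by the BH step-up
procedure at an FDR threshold (default 0.05). De novo mutation burden in
a gene set is tested against the expectation ``lambda = 2 * n_trios *
sum_g p_g`` built from per-gene, per-generation mutation probabilities
(one rate class per mutation consequence), with an upper-tail Poisson p.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import GeneSet

logger = logging.getLogger("escompare")

#: aggregated loss-of-function rate = nonsense + frameshift + canonical splice
LOF_COMPONENTS = ("p_non", "p_frameshift", "p_splice")
MUTATION_CLASSES = ("lof", "protein_altering")


# ---------------------------------------------------------------------------
# Fisher's exact test and BH
# ---------------------------------------------------------------------------


def fisher_exact(counts, sidedness: str = "greater") -> tuple[float, float]:
    """Fisher's exact test on a 2x2 table ``[[a, b], [c, d]]``.

    Returns ``(odds_ratio, p)`` with the sample odds ratio ad/bc (``inf``
    when bc = 0 and ad > 0, ``nan`` when a margin is zero). One-sided
    "greater" is the upper hypergeometric tail of the top-left cell;
    two-sided sums all tables with probability <= the observed one.
    A zero row or column margin makes the test uninformative: p = 1.
    """
    t = np.asarray(counts, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("counts must be a 2x2 table")
    if (t < 0).any() or not np.all(t == np.floor(t)):
        raise ValueError("counts must be non-negative integers")
    t = t.astype(int)
    if t.sum() == 0:
        raise ValueError("table total must be positive")
    a, b, c, d = t.ravel()
    if b * c == 0:
        odds = math.inf if a * d > 0 else math.nan
    else:
        odds = a * d / (b * c)
    if min(a + b, c + d, a + c, b + d) == 0:
        logger.warning("fisher_exact: zero margin; p = 1, odds ratio undefined")
        return math.nan, 1.0
    alternative = "greater" if sidedness == "greater" else "two-sided"
    _, p = stats.fisher_exact(t, alternative=alternative)
    return odds, float(min(p, 1.0))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), in input
    order: ``q_(i) = min_{j >= i} m * p_(j) / j`` capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([])
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


@dataclass
class EnrichmentResult:
    """One category's 2x2 enrichment summary.

    Counts: (query & category, query only, category only, neither); they
    sum to the universe size. ``odds_ratio`` is the sample odds ratio
    (``inf`` for an empty off-diagonal, ``nan`` for a zero margin).
    """

    category: str
    n_query_in: int
    n_query_out: int
    n_other_in: int
    n_other_out: int
    odds_ratio: float
    p: float
    q: float = math.nan
    significant: bool = False

    def as_dict(self) -> dict:
        return {
            "category": self.category,
            "query_in": self.n_query_in, "query_out": self.n_query_out,
            "other_in": self.n_other_in, "other_out": self.n_other_out,
            "odds_ratio": self.odds_ratio, "p": self.p, "q": self.q,
            "significant": self.significant,
        }


def set_enrichment(query: GeneSet, categories: pd.Series, universe: GeneSet,
                   sidedness: str = "greater", alpha: float = 0.05
                   ) -> list[EnrichmentResult]:
    """Fisher enrichment of *query* against every category, BH-corrected.

    ``categories`` maps gene -> category label; genes of the universe not
    in the map contribute only to the background. Query genes outside the
    universe are dropped with a logged count.
    """
    if len(universe) == 0:
        raise ValueError("empty universe")
    uni = universe.as_set()
    q_genes = query.as_set() & uni
    n_dropped = len(query.as_set()) - len(q_genes)
    if n_dropped:
        logger.info("set_enrichment: dropped %d query genes outside universe", n_dropped)
    cats = categories[categories.index.isin(uni)]
    n_universe = len(uni)
    n_query = len(q_genes)
    results: list[EnrichmentResult] = []
    for cat in sorted(pd.unique(cats)):
        members = set(cats.index[cats == cat])
        a = len(q_genes & members)
        b = n_query - a
        c = len(members) - a
        d = n_universe - a - b - c
        odds, p = fisher_exact([[a, b], [c, d]], sidedness=sidedness)
        results.append(EnrichmentResult(str(cat), a, b, c, d, odds, p))
    if results:
        qvals = bh_adjust([r.p for r in results])
        for r, qv in zip(results, qvals):
            r.q = float(qv)
            r.significant = bool(qv < alpha)
    return results


def enrichment_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([r.as_dict() for r in results])


# ---------------------------------------------------------------------------
# De novo mutation expectation test
# ---------------------------------------------------------------------------


@dataclass
class DeNovoModel:
    """Per-gene de novo mutation probabilities plus trio-study observations.

    ``rates`` is indexed by gene with one column per mutation class
    (``p_lof``, ``p_mis``; optionally the LOF components ``p_non``,
    ``p_frameshift``, ``p_splice`` which are summed into ``p_lof``). Each
    probability is the per-generation chance of a de novo event of that
    class anywhere in the gene's coding sequence, obtained by summing
    per-base mutation probabilities. ``observed`` maps class -> count of
    de novo events seen in the gene set of interest across ``n_trios``
    parent-offspring trios.
    """

    rates: pd.DataFrame
    n_trios: int
    observed: dict[str, int] | None = None

    def __post_init__(self) -> None:
        if "p_lof" not in self.rates.columns:
            comps = [c for c in LOF_COMPONENTS if c in self.rates.columns]
            if not comps:
                raise ValueError("rates need p_lof or its components "
                                 f"{LOF_COMPONENTS}")
            self.rates = self.rates.assign(p_lof=self.rates[comps].sum(axis=1))
        if "p_mis" not in self.rates.columns:
            raise ValueError("rates need a p_mis column")
        if (self.rates[["p_lof", "p_mis"]] < 0).any().any():
            raise ValueError("mutation probabilities must be >= 0")
        if self.observed is not None:
            for cls, n in self.observed.items():
                if n < 0 or n != int(n):
                    raise ValueError(f"observed count for {cls} must be a "
                                     "non-negative integer")

    def class_column(self, mclass: str) -> str:
        if mclass == "lof":
            return "p_lof"
        if mclass == "protein_altering":
            return "p_mis"
        raise ValueError(f"unknown mutation class {mclass!r}; "
                         f"expected one of {MUTATION_CLASSES}")


def denovo_expected(model: DeNovoModel, gene_set: GeneSet, mclass: str) -> float:
    """Expected de novo count: ``lambda = 2 * n_trios * sum_{g in set} p_g``
    (two transmitted haplotypes per trio). Genes absent from the rate table
    are dropped with a logged count."""
    if model.n_trios <= 0:
        raise ValueError("n_trios must be positive")
    col = model.class_column(mclass)
    present = [g for g in gene_set if g in model.rates.index]
    n_absent = len(gene_set) - len(present)
    if n_absent:
        logger.info("denovo_expected: %d set genes absent from rate table", n_absent)
    total_p = float(model.rates.loc[present, col].sum()) if present else 0.0
    return 2.0 * model.n_trios * total_p


def denovo_test(observed: int, lam: float) -> float:
    """Upper-tail Poisson enrichment p-value: P(X >= observed | lambda).

    Returns 1 when nothing was observed (no evidence of burden).
    """
    if observed < 0:
        raise ValueError("observed count must be >= 0")
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    if observed == 0:
        return 1.0
    return float(stats.poisson.sf(observed - 1, lam))
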