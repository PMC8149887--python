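"""Seeded synthetic-data generators with planted ground truth.

Every input the comparison pipeline consumes can be generated here:
overlapping essential-gene sets, differential-expression tables with a
planted effect size in one fold-change direction, developmental expression
matrices with planted co-expression modules and temporal eigengene
patterns, per-gene de novo mutation rates with simulated trio counts, and
feature tables / risk lists with planted shifts or odds ratios. Each
generator is a pure function of its parameters and a seed, and records
what it planted in a :class:`SyntheticTruth` so recovery can be scored.

The background -log10 p distribution is Exponential with mean 1/ln(10),
which is exactly the -log10 transform of Uniform(0, 1) p-values; a planted
mean shift ``delta`` on that scale therefore corresponds to a pooled-SD
Cohen's d of ``delta * ln(10)``.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .enrichment import DeNovoModel, bh_adjust
from .features import FeatureTable
from .io import DETable, ExpressionMatrix, GeneSet

LN10 = math.log(10.0)

#: the three planted eigengene trajectory shapes
PATTERN_TEMPLATES = ("prenatal_rise_sustained", "low_prenatal_mid",
                     "prenatal_high_drop")

#: sizes matching the published screen-catalogue overlap (|A|, |B|, |A ∩ B|)
SCREEN_SHAPE = {"n_a": 3838, "n_b": 2149, "n_shared": 698,
               "universe_size": 20000}


@dataclass
class SyntheticTruth:
    """Everything a generator planted, serializable next to its dataset."""

    seed: int
    set_sizes: dict | None = None
    planted_d: float | None = None
    planted_delta: float | None = None
    direction: str | None = None
    target_set: str | None = None
    module_membership: dict | None = None
    pattern_labels: dict | None = None
    planted_odds_ratio: float | None = None
    planted_shift: float | None = None
    denovo_gamma: float | None = None
    extras: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2,
                                         sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        return cls(**json.loads(Path(path).read_text()))


def _gene_names(n: int, prefix: str = "G") -> list[str]:
    width = len(str(n))
    return [f"{prefix}{i:0{width}d}" for i in range(1, n + 1)]


def delta_for_d(d: float) -> float:
    """Mean shift on the -log10 p scale giving pooled-SD Cohen's d = *d*
    when the background scores are Exponential(mean 1/ln 10)."""
    return d / LN10


# ---------------------------------------------------------------------------
# Essential-gene sets
# ---------------------------------------------------------------------------


def gen_essential_sets(n_a: int, n_b: int, n_shared: int, universe_size: int,
                       seed: int) -> tuple[GeneSet, GeneSet, GeneSet, SyntheticTruth]:
    """Two gene sets with exact sizes and overlap, sampled from a synthetic
    gene universe. Returns ``(A, B, universe, truth)``."""
    if n_shared > min(n_a, n_b):
        raise ValueError(f"n_shared={n_shared} exceeds min(n_a, n_b)={min(n_a, n_b)}")
    if n_a + n_b - n_shared > universe_size:
        raise ValueError(f"sets need {n_a + n_b - n_shared} distinct genes but "
                         f"universe has only {universe_size}")
    rng = np.random.default_rng(seed)
    genes = np.array(_gene_names(universe_size))
    picked = rng.choice(universe_size, size=n_a + n_b - n_shared, replace=False)
    a_only = picked[: n_a - n_shared]
    shared = picked[n_a - n_shared: n_a]
    b_only = picked[n_a:]
    set_a = GeneSet.from_iterable("A", genes[np.concatenate([a_only, shared])])
    set_b = GeneSet.from_iterable("B", genes[np.concatenate([b_only, shared])])
    universe = GeneSet.from_iterable("universe", genes)
    truth = SyntheticTruth(seed=seed, set_sizes={"n_a": n_a, "n_b": n_b,
                                                 "n_shared": n_shared,
                                                 "universe_size": universe_size})
    return set_a, set_b, universe, truth


# ---------------------------------------------------------------------------
# Differential-expression tables
# ---------------------------------------------------------------------------


def gen_de_table(universe: GeneSet, target_set: GeneSet, direction: str,
                 delta: float, seed: int) -> tuple[DETable, SyntheticTruth]:
    """DE table with uniform null p-values and a planted -log10 p mean
    shift ``delta`` for target-set genes whose fold change lies in
    *direction*.

    Fold-change signs are Bernoulli(1/2) independent of p (magnitudes are
    |N(0, 1)|, irrelevant downstream); the background -log10 p is
    Exponential(mean 1/ln 10), i.e. p ~ Uniform(0, 1). The adjusted-p
    column is the BH correction of the raw column.
    """
    if delta < 0:
        raise ValueError("delta must be >= 0")
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    if not target_set.as_set() <= universe.as_set():
        raise ValueError("target_set must be a subset of the universe")
    rng = np.random.default_rng(seed)
    genes = np.array(universe.genes)
    n = len(genes)
    score = rng.exponential(scale=1.0 / LN10, size=n)
    signs = rng.choice([1.0, -1.0], size=n)
    log2fc = signs * np.abs(rng.standard_normal(n))
    in_target = np.isin(genes, np.array(target_set.genes))
    dir_mask = signs > 0 if direction == "up" else signs < 0
    score = score + delta * (in_target & dir_mask)
    pvals = np.power(10.0, -score)
    padj = bh_adjust(pvals)
    table = DETable(pd.DataFrame({"gene": genes, "log2fc": log2fc,
                                  "pvalue": pvals, "padj": padj}))
    truth = SyntheticTruth(seed=seed, planted_delta=delta,
                           planted_d=delta * LN10, direction=direction,
                           target_set=target_set.name)
    return table, truth


# ---------------------------------------------------------------------------
# Developmental expression with planted modules
# ---------------------------------------------------------------------------


def _pattern_template(pattern: str, n_pre: int, n_post: int) -> np.ndarray:
    """Raw trajectory over (prenatal, postnatal) samples, before
    standardization. Prenatal position runs 0..1 with age."""
    t = np.linspace(0.0, 1.0, n_pre)
    if pattern == "prenatal_rise_sustained":
        pre, post = t, np.full(n_post, 1.0)
    elif pattern == "prenatal_high_drop":
        pre, post = 1.0 - t, np.full(n_post, 0.0)
    elif pattern == "low_prenatal_mid":
        pre, post = np.zeros(n_pre), np.full(n_post, 0.5)
    else:
        raise ValueError(f"unknown pattern {pattern!r}; "
                         f"expected one of {PATTERN_TEMPLATES}")
    tmpl = np.concatenate([pre, post])
    return (tmpl - tmpl.mean()) / tmpl.std(ddof=0)


def gen_expression(module_sizes, pattern_labels, n_prenatal: int,
                   n_postnatal: int, snr: float, seed: int,
                   n_background: int = 0
                   ) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Expression matrix with planted co-expression modules.

    Each module's genes follow one of the three temporal templates:
    ``gene = loading * template + noise`` with loadings Uniform(0.5, 1) and
    per-gene noise SD ``loading / snr`` (templates have unit SD), so every
    planted gene has the requested signal-to-noise ratio. Background genes
    are pure N(0, 1) noise. Prenatal samples span 50-260 post-conception
    days, postnatal samples 270-20000, both evenly spaced.
    """
    module_sizes = list(module_sizes)
    pattern_labels = list(pattern_labels)
    if len(module_sizes) != len(pattern_labels):
        raise ValueError("module_sizes and pattern_labels lengths differ")
    if any(s < 2 for s in module_sizes):
        raise ValueError("every module size must be >= 2")
    if snr <= 0:
        raise ValueError("snr must be positive")
    rng = np.random.default_rng(seed)
    n_samples = n_prenatal + n_postnatal
    ages = np.concatenate([np.linspace(50, 260, n_prenatal),
                           np.linspace(270, 20000, n_postnatal)])
    prenatal = np.concatenate([np.ones(n_prenatal, bool),
                               np.zeros(n_postnatal, bool)])
    n_genes = sum(module_sizes) + n_background
    genes = _gene_names(n_genes, prefix="EG")
    samples = [f"S{i:03d}" for i in range(1, n_samples + 1)]
    values = np.empty((n_genes, n_samples))
    membership: dict[str, int] = {}
    patterns: dict[str, str] = {}
    row = 0
    for mod_idx, (size, pattern) in enumerate(zip(module_sizes, pattern_labels),
                                              start=1):
        tmpl = _pattern_template(pattern, n_prenatal, n_postnatal)
        loadings = rng.uniform(0.5, 1.0, size=size)
        noise = rng.standard_normal((size, n_samples))
        values[row: row + size] = (loadings[:, None] * tmpl
                                   + (loadings / snr)[:, None] * noise)
        for g in genes[row: row + size]:
            membership[g] = mod_idx
        patterns[str(mod_idx)] = pattern
        row += size
    if n_background:
        values[row:] = rng.standard_normal((n_background, n_samples))
        for g in genes[row:]:
            membership[g] = 0
    em = ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=samples),
        age_days=pd.Series(ages, index=samples),
        prenatal=pd.Series(prenatal, index=samples),
    )
    truth = SyntheticTruth(seed=seed, module_membership=membership,
                           pattern_labels=patterns,
                           extras={"snr": snr, "n_prenatal": n_prenatal,
                                   "n_postnatal": n_postnatal})
    return em, truth


# ---------------------------------------------------------------------------
# De novo mutation data
# ---------------------------------------------------------------------------


def gen_denovo(rate_table_size: int, gene_set: GeneSet, n_trios: int,
               gamma: float, seed: int) -> tuple[DeNovoModel, SyntheticTruth]:
    """Per-gene mutation rates with simulated trio counts.

    Class rates (LOF and missense) are log-uniform in [1e-6, 1e-4] per
    gene per generation. Observed per-gene counts are Poisson with mean
    ``2 * n_trios * p_g``, multiplied by the enrichment factor ``gamma``
    for genes inside *gene_set*; the model's observed totals are the sums
    over the set.
    """
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    if n_trios <= 0:
        raise ValueError("n_trios must be positive")
    rng = np.random.default_rng(seed)
    genes = _gene_names(rate_table_size, prefix="DG")
    missing = [g for g in gene_set if g not in set(genes)]
    if missing and len(missing) == len(gene_set):
        # allow caller-supplied sets drawn from this generator's namespace
        raise ValueError("gene_set shares no genes with the rate table")
    rates = pd.DataFrame(
        {"p_lof": 10.0 ** rng.uniform(-6, -4, rate_table_size),
         "p_mis": 10.0 ** rng.uniform(-6, -4, rate_table_size)},
        index=pd.Index(genes, name="gene"))
    in_set = rates.index.isin(gene_set.as_set())
    factor = np.where(in_set, gamma, 1.0)
    observed = {}
    for cls, col in (("lof", "p_lof"), ("protein_altering", "p_mis")):
        per_gene = rng.poisson(2.0 * n_trios * rates[col].to_numpy() * factor)
        observed[cls] = int(per_gene[in_set].sum())
    model = DeNovoModel(rates=rates, n_trios=n_trios, observed=observed)
    truth = SyntheticTruth(seed=seed, denovo_gamma=gamma,
                           extras={"n_trios": n_trios,
                                   "set_size": int(in_set.sum())})
    return model, truth


def denovo_set(rate_table_size: int, set_size: int, seed: int,
               name: str = "denovo_set") -> GeneSet:
    """A random gene set drawn from :func:`gen_denovo`'s gene namespace."""
    rng = np.random.default_rng(seed)
    genes = np.array(_gene_names(rate_table_size, prefix="DG"))
    return GeneSet.from_iterable(
        name, genes[rng.choice(rate_table_size, size=set_size, replace=False)])


# ---------------------------------------------------------------------------
# Feature tables and risk lists
# ---------------------------------------------------------------------------


def gen_feature_table(universe: GeneSet, shifted_set: GeneSet, shift: float,
                      seed: int) -> tuple[FeatureTable, SyntheticTruth]:
    """Feature table with a planted location shift.

    Each gene gets a latent standard-normal constraint value, shifted by
    ``shift`` SD for genes in *shifted_set*. Columns derive from the latent
    value: pLI through a logistic squash to [0, 1], mutation probability
    and transcript length through log-scale maps, haploinsufficiency and
    GIMS as the latent value itself (independent noise per column keeps the
    columns distinct).
    """
    if not math.isfinite(shift):
        raise ValueError("shift must be finite")
    rng = np.random.default_rng(seed)
    genes = np.array(universe.genes)
    n = len(genes)
    in_set = np.isin(genes, np.array(shifted_set.genes))

    def latent() -> np.ndarray:
        return rng.standard_normal(n) + shift * in_set

    pli = 1.0 / (1.0 + np.exp(-latent()))
    mut_p = 10.0 ** (-5.0 + 0.5 * latent())
    hi = latent()
    tlen = np.maximum(1, np.round(10.0 ** (3.3 + 0.25 * latent()))).astype(int)
    gims = latent()
    table = FeatureTable(pd.DataFrame(
        {"pli": pli, "mutation_probability": mut_p, "haploinsufficiency": hi,
         "transcript_length": tlen, "gims": gims},
        index=pd.Index(genes, name="gene")))
    truth = SyntheticTruth(seed=seed, planted_shift=shift,
                           target_set=shifted_set.name)
    return table, truth


def gen_risk_list(universe: GeneSet, enriched_set: GeneSet, list_size: int,
                  odds_ratio: float, seed: int, name: str = "risk"
                  ) -> tuple[GeneSet, SyntheticTruth]:
    """Risk-gene list whose overlap with *enriched_set* has the planted
    odds ratio in expectation.

    Membership probabilities p1 (inside the enriched set) and p0 (outside)
    are chosen so that the odds ratio (p1/(1-p1)) / (p0/(1-p0)) equals
    ``odds_ratio`` and the expected list size equals ``list_size``.
    """
    if odds_ratio <= 0:
        raise ValueError("odds_ratio must be positive")
    rng = np.random.default_rng(seed)
    genes = np.array(universe.genes)
    n = len(genes)
    in_set = np.isin(genes, np.array(enriched_set.genes))
    n1, n0 = int(in_set.sum()), int(n - in_set.sum())
    if list_size >= n:
        raise ValueError("list_size must be smaller than the universe")

    def expected_size(p0: float) -> float:
        odds0 = p0 / (1 - p0)
        p1 = odds_ratio * odds0 / (1 + odds_ratio * odds0)
        return n0 * p0 + n1 * p1

    lo, hi = 1e-12, 1 - 1e-12
    for _ in range(200):  # bisection on the base rate
        mid = (lo + hi) / 2
        if expected_size(mid) < list_size:
            lo = mid
        else:
            hi = mid
    p0 = (lo + hi) / 2
    odds0 = p0 / (1 - p0)
    p1 = odds_ratio * odds0 / (1 + odds_ratio * odds0)
    probs = np.where(in_set, p1, p0)
    member = rng.random(n) < probs
    risk = GeneSet.from_iterable(name, genes[member])
    truth = SyntheticTruth(seed=seed, planted_odds_ratio=odds_ratio,
                           target_set=enriched_set.name,
                           extras={"p_in": p1, "p_out": p0,
                                   "expected_size": float(expected_size(p0))})
    return risk, truth
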