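"""Per-gene feature comparisons between two gene sets and tissue-panel
enrichment.

Features such as pLI (loss-of-function intolerance), per-generation
mutation probability, haploinsufficiency score, transcript length and the
GIMS negative-selection metric are consumed as published columns, never
recomputed. Two-set comparisons reuse the two-sided Wilcoxon rank-sum test
and pooled-SD Cohen's d on the raw feature values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .decompare import cohens_d_pooled, wilcoxon_rank_sum
from .enrichment import EnrichmentResult, set_enrichment
from .io import GeneSet

logger = logging.getLogger("escompare")

KNOWN_FEATURES = ("pli", "mutation_probability", "haploinsufficiency",
                  "transcript_length", "gims")


@dataclass
class FeatureTable:
    """Gene-indexed table of constraint/feature columns; any value may be
    missing per gene. pLI is validated to [0, 1] and transcript length to
    positive values where present."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if "pli" in self.data.columns:
            pli = self.data["pli"].dropna()
            if ((pli < 0) | (pli > 1)).any():
                raise ValueError("pli values must lie in [0, 1]")
        if "transcript_length" in self.data.columns:
            tl = self.data["transcript_length"].dropna()
            if (tl <= 0).any() or not np.all(tl == np.floor(tl)):
                raise ValueError("transcript_length must be a positive integer")

    @classmethod
    def from_tsv(cls, path) -> "FeatureTable":
        df = pd.read_csv(path, sep="\t")
        if "gene" not in df.columns:
            raise ValueError(f"{path}: feature table needs a gene column")
        df["gene"] = df["gene"].astype(str).str.strip()
        df = df.drop_duplicates("gene", keep="first").set_index("gene")
        return cls(df)


@dataclass
class FeatureComparison:
    feature: str
    n_y: int
    n_x: int
    median_y: float
    median_x: float
    p_wilcoxon: float
    d: float | None

    def as_dict(self) -> dict:
        return {"feature": self.feature, "n_y": self.n_y, "n_x": self.n_x,
                "median_y": self.median_y, "median_x": self.median_x,
                "p_wilcoxon": self.p_wilcoxon, "cohens_d": self.d}


def compare_feature(table: FeatureTable, set_y: GeneSet, set_x: GeneSet,
                    feature: str) -> FeatureComparison:
    """Two-sided Wilcoxon + pooled-SD Cohen's d on one feature's raw values
    between two gene sets. Genes missing the feature are dropped (logged);
    d > 0 means higher values in the first (Y) set."""
    if feature not in table.data.columns:
        raise ValueError(f"feature {feature!r} absent from table; "
                         f"available: {list(table.data.columns)}")
    col = table.data[feature]
    vals_y = col[col.index.isin(set_y.as_set())].dropna()
    vals_x = col[col.index.isin(set_x.as_set())].dropna()
    n_missing = (len(set_y.as_set() & set(col.index)) - len(vals_y)
                 + len(set_x.as_set() & set(col.index)) - len(vals_x))
    if n_missing:
        logger.info("compare_feature(%s): dropped %d genes with missing values",
                    feature, n_missing)
    if len(vals_y) < 2 or len(vals_x) < 2:
        raise ValueError(f"feature {feature!r}: need >= 2 genes with values "
                         f"per set, got {len(vals_y)} and {len(vals_x)}")
    y, x = vals_y.to_numpy(float), vals_x.to_numpy(float)
    _, p = wilcoxon_rank_sum(y, x)
    d = cohens_d_pooled(y, x).d
    return FeatureComparison(feature=feature, n_y=len(y), n_x=len(x),
                             median_y=float(np.median(y)),
                             median_x=float(np.median(x)),
                             p_wilcoxon=p, d=d)


def tissue_enrichment(query: GeneSet, panel: pd.Series, universe: GeneSet,
                      sidedness: str = "greater", alpha: float = 0.05
                      ) -> list[EnrichmentResult]:
    """Fisher enrichment of *query* across a gene -> tissue panel; a thin
    wrapper over :func:`escompare.enrichment.set_enrichment`."""
    return set_enrichment(query, panel, universe, sidedness=sidedness,
                          alpha=alpha)
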