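"""Ortholog mapping and the three-way partition of two essential-gene sets.

A genome-wide in vivo neuronal screen reports essential genes as mouse
symbols; cancer-cell-line screens report human symbols. The mouse list is
first mapped to human orthologs, then the two human lists are split into
set-specific blocks and a shared block by exact set algebra.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .io import GeneSet

logger = logging.getLogger("escompare")


@dataclass
class OrthologMap:
    """Source->target symbol pairs (e.g. mouse->human). One source may map
    to several targets and vice versa; pairs are unique."""

    pairs: tuple[tuple[str, str], ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: dict[tuple[str, str], None] = {}
        for s, t in self.pairs:
            seen.setdefault((s, t))
        self.pairs = tuple(seen)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "OrthologMap":
        df = pd.read_csv(path, sep="\t")
        if not {"source", "target"} <= set(df.columns):
            raise ValueError(f"{path}: ortholog map needs columns source, target; "
                             f"found {list(df.columns)}")
        pairs = tuple((str(s).strip(), str(t).strip())
                      for s, t in zip(df["source"], df["target"]))
        return cls(pairs, provenance=str(path))

    def targets_of(self, source: str) -> tuple[str, ...]:
        return tuple(t for s, t in self.pairs if s == source)


def map_orthologs(source_set: GeneSet, ortholog_map: OrthologMap) -> GeneSet:
    """Map every source symbol to the union of its targets.

    One-to-many relations expand to all targets; many-to-one collapse by set
    union; unmapped sources are dropped with a logged count. The result may
    be empty (with a warning) but mapping with an empty map is an error.
    """
    if not ortholog_map.pairs:
        raise ValueError("ortholog map is empty")
    by_source: dict[str, list[str]] = {}
    for s, t in ortholog_map.pairs:
        by_source.setdefault(s, []).append(t)
    mapped: list[str] = []
    n_unmapped = 0
    for g in source_set:
        if g in by_source:
            mapped.extend(by_source[g])
        else:
            n_unmapped += 1
    if n_unmapped:
        logger.info("map_orthologs: %d of %d source symbols unmapped",
                    n_unmapped, len(source_set))
    result = GeneSet.from_iterable(f"{source_set.name}_orthologs", mapped)
    if not result.genes:
        logger.warning("map_orthologs: empty result for %s", source_set.name)
    return result


@dataclass
class Partition:
    """Three pairwise-disjoint blocks of two gene sets: A-specific, B-specific
    and shared (A∩B). a_specific ∪ shared = A and b_specific ∪ shared = B."""

    a_specific: GeneSet
    b_specific: GeneSet
    shared: GeneSet

    def counts(self) -> dict[str, int]:
        return {"a_specific": len(self.a_specific),
                "b_specific": len(self.b_specific),
                "shared": len(self.shared)}

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.counts()])


def partition_sets(set_a: GeneSet, set_b: GeneSet) -> Partition:
    """Exact set algebra: (A \\ B, B \\ A, A ∩ B).

    Identical inputs yield empty specific blocks; order within each block
    follows the corresponding input set.
    """
    if not set_a.genes or not set_b.genes:
        raise ValueError("both input sets must be non-empty")
    part = Partition(
        a_specific=set_a.difference(set_b),
        b_specific=set_b.difference(set_a),
        shared=set_a.intersection(set_b),
    )
    logger.info("partition_sets: |A|=%d |B|=%d -> a_specific=%d b_specific=%d shared=%d",
                len(set_a), len(set_b), *part.counts().values())
    return part
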