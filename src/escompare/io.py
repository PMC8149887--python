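"""Readers, writers, and run configuration for the comparison pipeline.

All tabular inputs and outputs are plain TSV with a header line. Gene
lists are one symbol per line; gene-set collections use the GMT dialect
(tab-separated: name, description, members...). No science lives here.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("escompare")

#: number of significant digits used when writing floating-point output
FLOAT_DIGITS = 6


def _fmt(x) -> str:
    if isinstance(x, float):
        return f"{x:.{FLOAT_DIGITS}g}"
    return str(x)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

_P_COLUMNS = ("raw", "adjusted")
_SIDEDNESS = ("greater", "two-sided")


@dataclass
class RunConfig:
    """Pipeline-wide tunables.

    Defaults follow the published analysis where it states a value: the
    soft-thresholding power (15), minimum module size (30), module-eigengene
    merge cutoff (0.9), permutation count (1000) and FDR threshold (0.05).
    ``p_column`` selects whether raw or BH-adjusted differential-expression
    p-values feed the -log10 comparison; ``neglog10_floor`` is the smallest
    p representable before the -log10 transform (p below it is floored).
    """

    seed: int = 0
    n_permutations: int = 1000
    alpha: float = 0.05
    p_column: str = "raw"
    fisher_sidedness: str = "greater"
    soft_power: float = 15.0
    min_module_size: int = 30
    merge_threshold: float = 0.9
    neglog10_floor: float = 1e-300

    def __post_init__(self) -> None:
        if self.p_column not in _P_COLUMNS:
            raise ValueError(f"p_column must be one of {_P_COLUMNS}, got {self.p_column!r}")
        if self.fisher_sidedness not in _SIDEDNESS:
            raise ValueError(
                f"fisher_sidedness must be one of {_SIDEDNESS}, got {self.fisher_sidedness!r}"
            )
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.soft_power <= 0:
            raise ValueError("soft_power must be positive")
        if self.min_module_size < 1:
            raise ValueError("min_module_size must be >= 1")
        if not 0 < self.merge_threshold <= 1:
            raise ValueError("merge_threshold must be in (0, 1]")
        if not 0 < self.neglog10_floor <= 1:
            raise ValueError("neglog10_floor must be in (0, 1]")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def digest(self) -> str:
        """Stable hash of the configuration, for run logs."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Gene sets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneSet:
    """A named, ordered, duplicate-free collection of gene identifiers.

    Identifiers are matched as exact, case-sensitive strings throughout the
    package; no alias resolution is attempted. Insertion order is preserved
    so that outputs are deterministic.
    """

    name: str
    genes: tuple[str, ...]
    _members: frozenset = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "_members", frozenset(self.genes))

    @classmethod
    def from_iterable(cls, name: str, genes) -> "GeneSet":
        seen: dict[str, None] = {}
        for g in genes:
            g = str(g).strip()
            if g:
                seen.setdefault(g)
        return cls(name, tuple(seen))

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, g: object) -> bool:
        return g in self._members

    def __iter__(self):
        return iter(self.genes)

    def as_set(self) -> frozenset:
        return self._members

    def intersection(self, other: "GeneSet") -> "GeneSet":
        keep = other.as_set()
        return GeneSet(f"{self.name}&{other.name}", tuple(g for g in self.genes if g in keep))

    def difference(self, other: "GeneSet") -> "GeneSet":
        drop = other.as_set()
        return GeneSet(f"{self.name}-{other.name}", tuple(g for g in self.genes if g not in drop))


def read_gene_set(path: str | Path, format: str = "list") -> list[GeneSet]:
    """Read one (``list``) or several (``gmt``) gene sets from *path*.

    Duplicate symbols are collapsed with a logged count; symbols are
    whitespace-trimmed and case is preserved.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise ValueError(f"{path}: empty gene-set file")
    if format == "list":
        symbols = [line.strip() for line in text.splitlines() if line.strip()]
        gs = GeneSet.from_iterable(path.stem, symbols)
        dropped = len(symbols) - len(gs)
        if dropped:
            logger.warning("%s: collapsed %d duplicate symbols", path, dropped)
        return [gs]
    if format == "gmt":
        sets: list[GeneSet] = []
        for lineno, line in enumerate(text.splitlines(), start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: malformed GMT row at line {lineno}: "
                                 f"expected >=3 tab-separated fields, got {len(fields)}")
            name, _desc, *members = fields
            gs = GeneSet.from_iterable(name, members)
            dropped = len([m for m in members if m.strip()]) - len(gs)
            if dropped:
                logger.warning("%s line %d (%s): collapsed %d duplicates", path, lineno, name, dropped)
            sets.append(gs)
        if not sets:
            raise ValueError(f"{path}: GMT file contains no sets")
        return sets
    raise ValueError(f"unknown gene-set format {format!r}")


def write_gene_set(gs: GeneSet, path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in gs.genes))


def write_gmt(sets: Sequence[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, "na", *gs.genes]) + "\n")


# ---------------------------------------------------------------------------
# Differential-expression tables
# ---------------------------------------------------------------------------

#: accepted header names for each required DE column, lowercase
DE_COLUMN_SYNONYMS: dict[str, tuple[str, ...]] = {
    "gene": ("gene", "gene_id", "symbol", "gene_symbol", "id"),
    "log2fc": ("log2fc", "log2foldchange", "lfc", "logfc"),
    "pvalue": ("pvalue", "p", "pval", "p_value"),
    "padj": ("padj", "adj_p", "adjusted_p", "qvalue", "fdr", "p_adj"),
}


@dataclass
class DETable:
    """Per-gene differential-expression results, as produced by standard DE
    tools (one row per gene: log2 fold change, raw p, BH-adjusted p)."""

    data: pd.DataFrame  # columns: gene, log2fc, pvalue, padj; gene unique

    def __len__(self) -> int:
        return len(self.data)

    @property
    def genes(self) -> pd.Series:
        return self.data["gene"]


def read_de_table(path: str | Path, p_column: str = "raw",
                  synonyms: dict[str, tuple[str, ...]] | None = None) -> DETable:
    """Read a DE result TSV; see :data:`DE_COLUMN_SYNONYMS` for accepted
    header names. Rows missing the selected p-value are dropped (logged);
    for duplicated gene ids the first occurrence wins."""
    syn = synonyms or DE_COLUMN_SYNONYMS
    df = pd.read_csv(path, sep="\t")
    lower = {c.lower(): c for c in df.columns}
    rename = {}
    for canonical, names in syn.items():
        found = next((lower[n] for n in names if n in lower), None)
        if found is None:
            raise ValueError(
                f"{path}: missing required column {canonical!r} "
                f"(accepted names {list(names)}); found columns {list(df.columns)}"
            )
        rename[found] = canonical
    df = df.rename(columns=rename)[["gene", "log2fc", "pvalue", "padj"]].copy()
    df["gene"] = df["gene"].astype(str).str.strip()
    for col in ("log2fc", "pvalue", "padj"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    sel = "pvalue" if p_column == "raw" else "padj"
    n0 = len(df)
    df = df.dropna(subset=[sel])
    if len(df) < n0:
        logger.warning("%s: dropped %d rows with missing %s", path, n0 - len(df), sel)
    n0 = len(df)
    df = df.drop_duplicates(subset="gene", keep="first").reset_index(drop=True)
    if len(df) < n0:
        logger.warning("%s: dropped %d duplicated gene ids (first occurrence kept)", path, n0 - len(df))
    bad = df[["pvalue", "padj"]].stack().dropna()
    if ((bad < 0) | (bad > 1)).any():
        raise ValueError(f"{path}: p-values outside [0, 1]")
    return DETable(df)


def write_de_table(table: DETable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index=False,
                      float_format=f"%.{FLOAT_DIGITS}g")


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Gene x sample expression with per-sample developmental metadata.

    ``age_days`` is post-conception days; ``prenatal`` flags samples taken
    before birth. Samples are kept in ascending-age order. ``zero_variance``
    flags constant genes (they are retained; network steps drop them).
    """

    values: pd.DataFrame            # genes x samples
    age_days: pd.Series             # indexed by sample
    prenatal: pd.Series             # bool, indexed by sample

    def __post_init__(self) -> None:
        if not self.values.columns.equals(self.age_days.index):
            raise ValueError("sample order mismatch between values and metadata")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def zero_variance(self) -> pd.Series:
        return self.values.std(axis=1, ddof=1) == 0

    def sorted_by_age(self) -> "ExpressionMatrix":
        order = self.age_days.sort_values(kind="stable").index
        return ExpressionMatrix(self.values[order], self.age_days[order], self.prenatal[order])


def read_expression(matrix_path: str | Path, metadata_path: str | Path) -> ExpressionMatrix:
    """Read an expression TSV (first column = gene id) and its sample
    metadata TSV (columns: sample, age_days, prenatal). Samples are sorted
    by ascending age; constant genes are flagged but retained."""
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    meta = pd.read_csv(metadata_path, sep="\t")
    required = {"sample", "age_days", "prenatal"}
    if not required <= set(meta.columns):
        raise ValueError(f"{metadata_path}: metadata needs columns {sorted(required)}, "
                         f"found {list(meta.columns)}")
    meta = meta.set_index("sample")
    mat_samples, meta_samples = set(values.columns), set(meta.index)
    if mat_samples != meta_samples:
        only_mat = sorted(mat_samples - meta_samples)
        only_meta = sorted(meta_samples - mat_samples)
        raise ValueError(
            f"sample-id mismatch: only in matrix {only_mat}; only in metadata {only_meta}"
        )
    meta = meta.loc[values.columns]
    prenatal = meta["prenatal"].astype(bool)
    em = ExpressionMatrix(values, meta["age_days"].astype(float), prenatal).sorted_by_age()
    n_const = int(em.zero_variance.sum())
    if n_const:
        logger.warning("%s: %d zero-variance genes flagged", matrix_path, n_const)
    return em


def write_expression(em: ExpressionMatrix, matrix_path: str | Path,
                     metadata_path: str | Path) -> None:
    em.values.to_csv(matrix_path, sep="\t", float_format=f"%.{FLOAT_DIGITS}g",
                     index_label="gene")
    meta = pd.DataFrame({"sample": em.samples, "age_days": em.age_days.values,
                         "prenatal": em.prenatal.values})
    meta.to_csv(metadata_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Generic TSV helpers and run log
# ---------------------------------------------------------------------------


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=f"%.{FLOAT_DIGITS}g")


def write_run_log(path: str | Path, config: RunConfig, extra: dict | None = None) -> None:
    """Machine-readable record of a run: seed, config hash, library versions."""
    import scipy

    payload = {
        "seed": config.seed,
        "config": config.to_dict(),
        "config_digest": config.digest(),
        "versions": {"numpy": np.__version__, "pandas": pd.__version__,
                     "scipy": scipy.__version__},
    }
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
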