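"""Post-homology-search logic: hit filtering, best-hit selection, and
grouping of significant transcripts by unique sequence description.

De novo transcriptome assemblies are redundant — several contigs are
often alternative assemblies or fragments of one transcript — so
significant contigs are collapsed onto the deduplicated textual
description of their best database hit, giving per-direction sets of
putative genes.  Descriptions are case-folded and whitespace-collapsed
before uniqueness.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Set

import pandas as pd

__all__ = [
    "AnnotConfig",
    "AnnotationGroups",
    "BLAST_COLUMNS",
    "read_hits",
    "filter_hits",
    "best_hit",
    "best_hits",
    "group_by_description",
    "annotation_rate",
]

#: the standard 12-column tabular layout plus a trailing description
BLAST_COLUMNS = [
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
]


@dataclass(frozen=True)
class AnnotConfig:
    max_hits: int = 10
    evalue_max: float = 1e-10
    min_unannotated_long_len: int = 1000

    def __post_init__(self) -> None:
        if self.max_hits < 1:
            raise ValueError("max_hits must be >= 1")


@dataclass
class AnnotationGroups:
    """Direction-wise unique-description sets for significant
    transcripts, plus tallies of the significant transcripts that carry
    no surviving hit."""

    up_descriptions: Set[str] = field(default_factory=set)
    down_descriptions: Set[str] = field(default_factory=set)
    unannotated_significant: int = 0
    unannotated_significant_long: int = 0

    @property
    def conflicts(self) -> Set[str]:
        """Descriptions significant in both directions."""
        return self.up_descriptions & self.down_descriptions


def read_hits(path, has_description: bool = True) -> pd.DataFrame:
    """Read a 12-column tabular hit file (optionally with a 13th
    description column)."""
    cols = BLAST_COLUMNS + (["description"] if has_description else [])
    return pd.read_csv(path, sep="\t", names=cols, header=None)


def normalize_description(text: str) -> str:
    return re.sub(r"\s+", " ", str(text).strip()).casefold()


def _rank(hits: pd.DataFrame) -> pd.DataFrame:
    """Deterministic hit order: bitscore desc, then evalue asc, then
    subject id asc."""
    return hits.sort_values(
        ["bitscore", "evalue", "sseqid"], ascending=[False, True, True], kind="mergesort"
    )


def filter_hits(hits: pd.DataFrame, config: AnnotConfig = AnnotConfig()) -> pd.DataFrame:
    """Drop hits above the e-value ceiling, then keep at most
    ``max_hits`` per query by descending bit score."""
    kept = hits[hits["evalue"] <= config.evalue_max]
    if kept.empty:
        return kept
    return _rank(kept).groupby("qseqid", sort=False).head(config.max_hits)


def best_hit(hits: pd.DataFrame) -> pd.Series:
    """Single best hit for one query: maximal bit score, ties broken by
    minimal e-value then lexicographically smallest subject id."""
    if hits.empty:
        raise ValueError("best_hit of an empty hit set")
    return _rank(hits).iloc[0]


def best_hits(hits: pd.DataFrame) -> pd.DataFrame:
    """Best hit per query over a whole table (one row per query)."""
    if hits.empty:
        return hits
    return _rank(hits).groupby("qseqid", sort=False).head(1).set_index("qseqid")


def group_by_description(
    de: pd.DataFrame,
    best: Mapping[str, str] | pd.Series,
    config: AnnotConfig = AnnotConfig(),
) -> AnnotationGroups:
    """Collapse significant transcripts onto unique descriptions by
    direction.

    ``best`` maps transcript id -> best-hit description.  A description
    enters the up (down) set when at least one significant transcript
    with positive (negative) log2fc carries it; a description may sit
    in both sets.  Significant transcripts with no hit are tallied,
    with a sub-tally of those longer than ``min_unannotated_long_len``
    (requires a ``length`` column for the sub-tally).
    """
    groups = AnnotationGroups()
    sig = de[de["significant"]]
    has_len = "length" in de.columns
    for contig, row in sig.iterrows():
        desc = best.get(contig) if hasattr(best, "get") else None
        if desc is None or (isinstance(desc, float) and pd.isna(desc)):
            groups.unannotated_significant += 1
            if has_len and pd.notna(row["length"]) and row["length"] > config.min_unannotated_long_len:
                groups.unannotated_significant_long += 1
            continue
        desc = normalize_description(desc)
        if row["log2fc"] > 0:
            groups.up_descriptions.add(desc)
        elif row["log2fc"] < 0:
            groups.down_descriptions.add(desc)
    return groups


def annotation_rate(contigs: Iterable[str], best: Mapping[str, str] | pd.Series) -> float:
    """Fraction of contigs with at least one surviving hit."""
    ids = list(contigs)
    if not ids:
        raise ValueError("annotation_rate over an empty contig set")
    annotated = sum(1 for c in ids if c in best)
    return annotated / len(ids)
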