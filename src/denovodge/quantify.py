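"""Fragments-per-contig count matrices from SAM alignments.

Only QNAME, FLAG, RNAME are consumed from the alignment records; the
aligner is trusted for placement and multi-mapper assignment, so
counting is deterministic and order-independent.  Two count units are
supported: ``read`` (each mapped read adds 1) and ``fragment`` (a
proper pair with both mates on one contig adds 1; any other mapped
read adds 1 on its own contig).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import pandas as pd
import pysam

__all__ = [
    "QuantConfig",
    "count_sample",
    "build_matrix",
    "filter_low_count",
    "augment_reference",
    "read_count_matrix",
    "write_count_matrix",
]


@dataclass(frozen=True)
class QuantConfig:
    """Low-count filter threshold and counting unit.

    The published rule rejects any transcript with fewer than 10 mapped
    reads, pooled over all samples.
    """

    min_reads_per_contig: int = 10
    count_unit: str = "read"

    def __post_init__(self) -> None:
        if self.min_reads_per_contig < 0:
            raise ValueError("threshold must be >= 0")
        if self.count_unit not in ("read", "fragment"):
            raise ValueError("count_unit must be 'read' or 'fragment'")


def count_sample(
    sam_path,
    contigs: Iterable[str],
    unit: str = "read",
) -> Dict[str, int]:
    """Count mapped reads (or fragments) per contig for one sample.

    Every contig in ``contigs`` appears in the result, zero-filled when
    unseen.  A mapped record naming an unknown contig is an error.
    """
    if unit not in ("read", "fragment"):
        raise ValueError("unit must be 'read' or 'fragment'")
    counts = {c: 0 for c in contigs}
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped:
                continue
            name = rec.reference_name
            if name not in counts:
                raise ValueError(f"alignment references unknown contig {name!r}")
            if unit == "read":
                counts[name] += 1
            else:
                same_contig_pair = (
                    rec.is_paired
                    and rec.is_proper_pair
                    and not rec.mate_is_unmapped
                    and rec.next_reference_id == rec.reference_id
                )
                if same_contig_pair:
                    # one fragment per pair: count it on the first mate only
                    if rec.is_read1 or not rec.is_read2:
                        counts[name] += 1
                else:
                    counts[name] += 1
    return counts


def build_matrix(
    per_sample: Mapping[str, Mapping[str, int]],
    sample_order: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Assemble per-sample count dicts into a contig x sample table.

    Rows are sorted lexicographically by contig id; all samples must
    cover the same contig universe.
    """
    samples = list(sample_order) if sample_order is not None else list(per_sample)
    universes = {s: frozenset(per_sample[s]) for s in samples}
    first = universes[samples[0]]
    for s, u in universes.items():
        if u != first:
            raise ValueError(f"sample {s!r} covers a different contig universe")
    contigs = sorted(first)
    data = {s: [per_sample[s][c] for c in contigs] for s in samples}
    mat = pd.DataFrame(data, index=pd.Index(contigs, name="transcript_id"))
    if (mat.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    return mat


def filter_low_count(
    matrix: pd.DataFrame, config: QuantConfig = QuantConfig()
) -> Tuple[pd.DataFrame, int]:
    """Drop contigs whose pooled count across samples falls below the
    threshold; returns (kept matrix, number removed)."""
    keep = matrix.sum(axis=1) >= config.min_reads_per_contig
    return matrix.loc[keep], int((~keep).sum())


def augment_reference(
    contigs: Sequence, extra: Sequence, suffix: str = "_ext"
) -> Tuple[list, Dict[str, str]]:
    """Merge externally supplied sequences into a contig set.

    Returns the merged records plus a provenance map id -> 'assembly' |
    'external'.  Identifier collisions in the extras are renamed with
    ``suffix`` (records are shallow-copied; originals are untouched).
    """
    merged = list(contigs)
    provenance = {rec.id: "assembly" for rec in contigs}
    if len(provenance) != len(merged):
        raise ValueError("duplicate identifiers within the contig set")
    for rec in extra:
        new_id = rec.id
        while new_id in provenance:
            new_id = new_id + suffix
        if new_id != rec.id:
            rec = rec[:]  # SeqRecord slice copy
            rec.id = new_id
            rec.description = ""
        merged.append(rec)
        provenance[new_id] = "external"
    return merged, provenance


def write_count_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="transcript_id")


def read_count_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="transcript_id")
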