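"""Contig-set statistics and N50-plateau assembly selection.

N50 here is the classic assembly summary: the contig length L such
that contigs of length >= L contain at least half of the total
assembled bases.  ``select_k`` operationalizes the common practice of
choosing a de Bruijn k-mer size by scanning assemblies over a k range
and picking the largest k on the N50 plateau before the profile dips.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Sequence, Tuple

import numpy as np
from Bio import SeqIO

__all__ = [
    "AssemblyStats",
    "n50",
    "assembly_stats",
    "select_k",
    "length_bins",
    "contig_lengths",
    "removed_percent",
]


@dataclass(frozen=True)
class AssemblyStats:
    n_contigs: int
    mean_len: float
    n50: int
    min_len_applied: int = 0


def n50(lengths: Sequence[int]) -> int:
    """Smallest length L in the descending-sorted list whose cumulative
    sum reaches half the total (>= convention; L is always a member of
    the input)."""
    if len(lengths) == 0:
        raise ValueError("n50 of an empty length set is undefined")
    arr = np.sort(np.asarray(lengths, dtype=np.int64))[::-1]
    if np.any(arr <= 0):
        raise ValueError("contig lengths must be positive")
    half = arr.sum() / 2.0
    idx = int(np.searchsorted(np.cumsum(arr), half))
    return int(arr[idx])


def assembly_stats(lengths: Sequence[int], min_len: int = 0) -> AssemblyStats:
    """Count / mean / N50 after dropping contigs shorter than min_len."""
    arr = np.asarray(lengths, dtype=np.int64)
    kept = arr[arr >= min_len]
    if kept.size == 0:
        raise ValueError(f"no contigs survive the min_len={min_len} filter")
    return AssemblyStats(
        n_contigs=int(kept.size),
        mean_len=float(kept.mean()),
        n50=n50(kept),
        min_len_applied=min_len,
    )


def select_k(profile: Mapping[int, float], tol: float = 0.05) -> int:
    """Pick the largest k on the N50 plateau.

    The plateau is the maximal contiguous run (in increasing k) that
    contains the argmax and whose N50 values stay within ``tol`` of the
    maximum, i.e. n50 >= (1 - tol) * max.  The profile 'dips' where the
    run ends; the chosen k is the run's right edge.
    """
    if len(profile) < 2:
        raise ValueError("k profile needs at least two entries")
    ks = sorted(profile)
    vals = [profile[k] for k in ks]
    m = max(vals)
    thr = (1.0 - tol) * m
    peak = vals.index(m)
    right = peak
    while right + 1 < len(ks) and vals[right + 1] >= thr:
        right += 1
    return ks[right]


def length_bins(lengths: Iterable[int]) -> Tuple[int, int, int]:
    """Partition contig lengths into the volcano-plot colour bins:
    < 300 bp, 300-3000 bp inclusive, > 3000 bp."""
    arr = np.asarray(list(lengths), dtype=np.int64)
    if arr.size == 0:
        return (0, 0, 0)
    short = int((arr < 300).sum())
    long_ = int((arr > 3000).sum())
    return (short, int(arr.size) - short - long_, long_)


def contig_lengths(fasta_path) -> Dict[str, int]:
    """Sequence lengths keyed by identifier from a FASTA file."""
    return {rec.id: len(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}


def removed_percent(n_before: int, n_after: int) -> float:
    """Percentage of a set eliminated by a filter, from before/after counts."""
    if n_before <= 0 or n_after < 0 or n_after > n_before:
        raise ValueError("need 0 <= n_after <= n_before with n_before > 0")
    return 100.0 * (n_before - n_after) / n_before
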