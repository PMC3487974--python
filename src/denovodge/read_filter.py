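"""Quality-driven FASTQ filtration with paired-end bookkeeping.

Implements a Genome-Analyzer-era read-cleaning scheme for short
(~60 bp) reads:

1. reads containing uncalled bases (anything outside A/C/G/T) are
   rejected outright;
2. the Q2 reliability flag (``'B'`` in phred+64 encoding) marks
   everything from its first occurrence onward as untrustworthy, so the
   read is truncated there;
3. each remaining position is marked *failing* when its own score is at
   or below ``q_break`` (default 10) or when the mean score of the
   position and its immediate neighbours is at or below
   ``window_mean_break`` (default 20);
4. the read splits into maximal runs of passing positions and the
   longest run is kept, provided it is at least ``min_fragment_len``
   (default 49) bases long.

Pair integrity is maintained: when only one mate survives it is routed
to a single-end stream, and surviving pairs stay synchronized
record-for-record.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field, replace
from typing import IO, Iterable, Iterator, Optional, TextIO, Tuple

from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "ReadRecord",
    "FilterConfig",
    "FilterStats",
    "FilterOutcome",
    "QualityDecodeError",
    "PairingError",
    "decode_quality",
    "encode_quality",
    "filter_read",
    "filter_pair",
    "filter_files",
]

_OFFSETS = {"phred33": 33, "phred64": 64}
_MAX_SCORE = 60
_VALID_BASES = frozenset("ACGT")


class QualityDecodeError(ValueError):
    """A quality character falls outside the declared encoding's range."""


class PairingError(ValueError):
    """Mate identifiers do not agree."""


@dataclass
class ReadRecord:
    """One sequencing read with decoded per-base phred scores."""

    id: str
    bases: str
    quals: list[int]

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise ValueError(
                f"read {self.id!r}: {len(self.bases)} bases but "
                f"{len(self.quals)} quality scores"
            )

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for the filtration algorithm (defaults as published
    for 60 bp Illumina GA reads)."""

    q_break: int = 10
    window_mean_break: float = 20.0
    min_fragment_len: int = 49
    b_flag_score: int = 2
    apply_b_rule: bool = True
    encoding: str = "phred33"

    def __post_init__(self) -> None:
        if self.q_break < 0 or self.window_mean_break < 0:
            raise ValueError("thresholds must be non-negative")
        if self.min_fragment_len < 1:
            raise ValueError("min_fragment_len must be >= 1")
        if self.encoding not in _OFFSETS:
            raise ValueError(f"unknown encoding {self.encoding!r}")


@dataclass
class FilterStats:
    """Bookkeeping for one filtration run.

    Conservation: ``2*pairs_out + singles_out + rejected_uncalled +
    rejected_short == reads_in`` holds exactly.
    """

    reads_in: int = 0
    pairs_out: int = 0
    singles_out: int = 0
    rejected_uncalled: int = 0
    rejected_short: int = 0

    @property
    def rejected(self) -> int:
        return self.rejected_uncalled + self.rejected_short

    def check(self) -> None:
        total = 2 * self.pairs_out + self.singles_out + self.rejected
        if total != self.reads_in:
            raise AssertionError(
                f"conservation violated: {total} accounted != {self.reads_in} in"
            )


@dataclass(frozen=True)
class FilterOutcome:
    """Result of filtering a single read.

    ``kept`` is the surviving fragment (a contiguous substring of the
    input) or None; ``offset`` is the fragment's 0-based start in the
    original read; ``reason`` is 'uncalled' or 'short' for rejections.
    """

    kept: Optional[ReadRecord]
    offset: int = 0
    reason: Optional[str] = None

    @property
    def passed(self) -> bool:
        return self.kept is not None


def decode_quality(qual_string: str, encoding: str = "phred33") -> list[int]:
    """Decode a FASTQ quality string to integer phred scores.

    Raises :class:`QualityDecodeError` naming the first offending
    position if a character lies outside ``[offset, offset + 60]``.
    """
    try:
        offset = _OFFSETS[encoding]
    except KeyError:
        raise ValueError(f"unknown encoding {encoding!r}") from None
    scores = []
    for pos, ch in enumerate(qual_string):
        score = ord(ch) - offset
        if not 0 <= score <= _MAX_SCORE:
            raise QualityDecodeError(
                f"quality character {ch!r} at position {pos} is outside the "
                f"{encoding} range"
            )
        scores.append(score)
    return scores


def encode_quality(scores: Iterable[int], encoding: str = "phred33") -> str:
    """Inverse of :func:`decode_quality`."""
    offset = _OFFSETS[encoding]
    return "".join(chr(q + offset) for q in scores)


def _passing_positions(quals: list[int], config: FilterConfig) -> list[bool]:
    """Per-position pass/fail under the score and 3-window rules.

    The window mean at a terminus averages over the neighbours that
    exist (two values instead of three).
    """
    n = len(quals)
    passing = []
    for p in range(n):
        if quals[p] <= config.q_break:
            passing.append(False)
            continue
        lo = max(0, p - 1)
        hi = min(n, p + 2)
        window = quals[lo:hi]
        passing.append(sum(window) / len(window) > config.window_mean_break)
    return passing


def filter_read(read: ReadRecord, config: FilterConfig = FilterConfig()) -> FilterOutcome:
    """Apply the full filtration algorithm to one read.

    Rule order is fixed: uncalled-base rejection, then Q2 truncation,
    then score/window splitting, then longest-fragment selection
    (ties keep the 5'-most fragment).
    """
    if any(b not in _VALID_BASES for b in read.bases):
        return FilterOutcome(None, reason="uncalled")

    bases, quals = read.bases, read.quals
    if config.apply_b_rule and config.b_flag_score in quals:
        cut = quals.index(config.b_flag_score)
        bases, quals = bases[:cut], quals[:cut]

    passing = _passing_positions(quals, config)

    # longest maximal run of passing positions, 5'-most on ties
    best_start, best_len = 0, 0
    run_start = None
    for p, ok in enumerate(passing + [False]):
        if ok and run_start is None:
            run_start = p
        elif not ok and run_start is not None:
            run_len = p - run_start
            if run_len > best_len:
                best_start, best_len = run_start, run_len
            run_start = None

    if best_len < config.min_fragment_len:
        return FilterOutcome(None, reason="short")
    frag = ReadRecord(
        read.id,
        bases[best_start : best_start + best_len],
        quals[best_start : best_start + best_len],
    )
    return FilterOutcome(frag, offset=best_start)


def _pair_key(read_id: str) -> str:
    """Identifier with a trailing /1 or /2 mate tag stripped."""
    if len(read_id) > 1 and read_id[-2] == "/" and read_id[-1] in "12":
        return read_id[:-2]
    return read_id


def filter_pair(
    r1: ReadRecord, r2: ReadRecord, config: FilterConfig = FilterConfig()
) -> Tuple[str, list[FilterOutcome]]:
    """Filter both mates and route the survivors.

    Returns ``(routing, [outcome1, outcome2])`` where routing is
    'paired' (both survive), 'single' (exactly one survives; the orphan
    goes to the single-end stream) or 'dropped'.
    """
    if _pair_key(r1.id) != _pair_key(r2.id):
        raise PairingError(f"mate identifiers disagree: {r1.id!r} vs {r2.id!r}")
    o1, o2 = filter_read(r1, config), filter_read(r2, config)
    if o1.passed and o2.passed:
        routing = "paired"
    elif o1.passed or o2.passed:
        routing = "single"
    else:
        routing = "dropped"
    return routing, [o1, o2]


def _open_text(path, mode: str = "rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def _read_fastq(handle: TextIO, encoding: str) -> Iterator[ReadRecord]:
    for title, seq, qual in FastqGeneralIterator(handle):
        rid = title.split()[0]
        yield ReadRecord(rid, seq.upper(), decode_quality(qual, encoding))


def _write_record(handle: TextIO, rec: ReadRecord, encoding: str) -> None:
    handle.write(f"@{rec.id}\n{rec.bases}\n+\n{encode_quality(rec.quals, encoding)}\n")


def filter_files(
    in1,
    in2=None,
    *,
    config: FilterConfig = FilterConfig(),
    out_paired1=None,
    out_paired2=None,
    out_single=None,
) -> FilterStats:
    """Stream one or two FASTQ files through the filter.

    Output paths may be omitted (counting only).  Surviving single-end
    reads — orphans from pairs, or every survivor in single-stream mode
    — go to ``out_single``.  Gzip-transparent on ``.gz`` suffixes.
    Returns :class:`FilterStats`; the conservation identity is checked
    before returning.
    """
    stats = FilterStats()
    enc = config.encoding

    sinks: dict[str, Optional[TextIO]] = {}
    opened = []

    def _sink(path):
        if path is None:
            return None
        h = _open_text(path, "wt")
        opened.append(h)
        return h

    p1, p2, sg = _sink(out_paired1), _sink(out_paired2), _sink(out_single)
    try:
        with _open_text(in1) as h1:
            if in2 is None:
                for read in _read_fastq(h1, enc):
                    stats.reads_in += 1
                    out = filter_read(read, config)
                    if out.passed:
                        stats.singles_out += 1
                        if sg:
                            _write_record(sg, out.kept, enc)
                    elif out.reason == "uncalled":
                        stats.rejected_uncalled += 1
                    else:
                        stats.rejected_short += 1
            else:
                with _open_text(in2) as h2:
                    for r1, r2 in zip(
                        _read_fastq(h1, enc), _read_fastq(h2, enc), strict=True
                    ):
                        stats.reads_in += 2
                        routing, (o1, o2) = filter_pair(r1, r2, config)
                        for o in (o1, o2):
                            if not o.passed:
                                if o.reason == "uncalled":
                                    stats.rejected_uncalled += 1
                                else:
                                    stats.rejected_short += 1
                        if routing == "paired":
                            stats.pairs_out += 1
                            if p1:
                                _write_record(p1, o1.kept, enc)
                            if p2:
                                _write_record(p2, o2.kept, enc)
                        elif routing == "single":
                            stats.singles_out += 1
                            survivor = o1.kept if o1.passed else o2.kept
                            if sg:
                                _write_record(sg, survivor, enc)
    finally:
        for h in opened:
            h.close()
    stats.check()
    return stats
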