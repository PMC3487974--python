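"""Synthetic inputs with known truth for every pipeline stage.

The generators emulate an Illumina GA-era digital-gene-expression
study design on a non-model organism: short (60 bp) read pairs with
the quality pathologies of that platform generation (Q2 'B' tails,
uncalled bases, low-quality dips), a redundant fragmented contig set
standing in for a de novo assembly, negative-binomial counts for an
exposed-vs-pooled-reference contrast with a known differentially
expressed fraction, mock tabular homology hits, and a
dynamic-range-compressed microarray fold-change table.

Everything is driven by a ``TruthTable`` (per-gene expected level,
true log2 fold change, DE label, dispersion) against which recovery
can be scored exactly.  All generators are deterministic given their
seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .read_filter import ReadRecord, encode_quality

__all__ = [
    "QualityModel",
    "FragmentationModel",
    "simulate_truth",
    "simulate_counts",
    "simulate_transcripts",
    "fragment_transcriptome",
    "simulate_reads",
    "simulate_annotation",
    "simulate_probe_hits",
    "simulate_microarray",
    "simulate_alignments",
    "write_fasta",
    "write_paired_fastq",
    "write_sam",
]

_BASES = np.array(list("ACGT"))


def _check_prob(name: str, p: float) -> None:
    if not (np.isfinite(p) and 0.0 <= p <= 1.0):
        raise ValueError(f"{name} must be a probability in [0, 1], got {p}")


@dataclass(frozen=True)
class QualityModel:
    """Per-base quality profile with GA-era pathologies.

    Base qualities start near ``mean_start_q`` and decay linearly along
    the read; with probability ``b_tail_prob`` a read gets a Q2 tail
    whose length is drawn from ``b_tail_len_dist``; each base turns
    into an uncalled 'N' with probability ``n_prob``; with probability
    ``dip_prob`` a read gets one low-quality dip at a random position,
    its score drawn from ``dip_q_dist``.
    """

    mean_start_q: int = 35
    decay_per_base: float = 0.1
    b_tail_prob: float = 0.1
    b_tail_len_dist: Optional[Callable[[np.random.Generator], int]] = None
    n_prob: float = 0.002
    dip_prob: float = 0.1
    dip_q_dist: Optional[Callable[[np.random.Generator], int]] = None

    def __post_init__(self) -> None:
        for name in ("b_tail_prob", "n_prob", "dip_prob"):
            _check_prob(name, getattr(self, name))
        if not 0 <= self.mean_start_q <= 41:
            raise ValueError("mean_start_q must lie in [0, 41]")

    def draw_tail_len(self, rng: np.random.Generator) -> int:
        if self.b_tail_len_dist is not None:
            return int(self.b_tail_len_dist(rng))
        return int(rng.geometric(0.1))  # mean 10 bases

    def draw_dip_q(self, rng: np.random.Generator) -> int:
        if self.dip_q_dist is not None:
            return int(self.dip_q_dist(rng))
        return int(rng.integers(3, 11))  # low enough to break the read


@dataclass(frozen=True)
class FragmentationModel:
    """Redundancy model for a de novo assembly stand-in.

    With probability ``dup_rate`` a transcript yields an extra
    alternative contig; each emitted contig is independently replaced,
    with probability ``frag_rate``, by a contiguous sub-fragment whose
    length fraction is uniform on [min_frac, max_frac].
    """

    dup_rate: float = 0.3
    frag_rate: float = 0.4
    min_frac: float = 0.3
    max_frac: float = 0.9

    def __post_init__(self) -> None:
        _check_prob("dup_rate", self.dup_rate)
        _check_prob("frag_rate", self.frag_rate)
        if not 0.0 <= self.min_frac <= self.max_frac <= 1.0:
            raise ValueError("need 0 <= min_frac <= max_frac <= 1")


def simulate_truth(
    n_genes: int,
    frac_de: float,
    lfc_sd: float = 1.0,
    dispersion: float = 0.1,
    seed: int = 0,
    *,
    min_abs_lfc: float = 0.5,
    base_mean_median: float = 100.0,
    base_mean_log_sd: float = 1.0,
    base_mean_min: float = 1.0,
) -> pd.DataFrame:
    """Ground-truth table for a two-condition contrast.

    Exactly ``round(n_genes * frac_de)`` genes are differentially
    expressed; their log2 fold changes are drawn from a symmetric
    two-component distribution ``sign * (min_abs_lfc + |N(0, lfc_sd)|)``
    so no true effect is below ``min_abs_lfc`` (an undetectably small
    truth would make power statements meaningless).  Expected levels
    are log-normal (median ``base_mean_median``, log-sd
    ``base_mean_log_sd``), floored at ``base_mean_min``.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    _check_prob("frac_de", frac_de)
    for name, v in (("lfc_sd", lfc_sd), ("dispersion", dispersion)):
        if not (np.isfinite(v) and v >= 0):
            raise ValueError(f"{name} must be finite and >= 0")
    rng = np.random.default_rng(seed)
    base_mean = np.maximum(
        np.exp(rng.normal(math.log(base_mean_median), base_mean_log_sd, n_genes)),
        base_mean_min,
    )
    n_de = int(round(n_genes * frac_de))
    de_idx = rng.choice(n_genes, size=n_de, replace=False)
    lfc = np.zeros(n_genes)
    signs = rng.choice([-1.0, 1.0], size=n_de)
    lfc[de_idx] = signs * (min_abs_lfc + np.abs(rng.normal(0.0, lfc_sd, n_de)))
    return pd.DataFrame(
        {
            "gene_id": [f"g{i:05d}" for i in range(n_genes)],
            "base_mean": base_mean,
            "true_log2fc": lfc,
            "is_de": lfc != 0.0,
            "dispersion": dispersion,
        }
    ).set_index("gene_id", drop=False)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """NB(mean, var = mean + alpha*mean^2); Poisson when alpha = 0."""
    if alpha == 0.0:
        return rng.poisson(mean)
    size = 1.0 / alpha
    prob = size / (size + mean)
    return rng.negative_binomial(size, prob)


def simulate_counts(
    truth: pd.DataFrame,
    size_factors: Sequence[float],
    design: Sequence[str],
    seed: int = 0,
    *,
    exposed_label: str = "exposed",
    sample_names: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Per-gene, per-sample NB counts under the truth table.

    Sample j's mean for gene i is ``s_j * base_mean_i *
    2**(true_log2fc_i)`` in the exposed condition and
    ``s_j * base_mean_i`` in the reference.
    """
    s = np.asarray(size_factors, dtype=float)
    if (s <= 0).any() or not np.isfinite(s).all():
        raise ValueError("size factors must be positive and finite")
    if len(s) != len(design):
        raise ValueError("size_factors and design must have one entry per sample")
    labels = list(design)
    if len(set(labels)) < 2 or exposed_label not in labels:
        raise ValueError("design needs both conditions present")
    if sample_names is None:
        tally: dict[str, int] = {}
        sample_names = []
        for lab in labels:
            tally[lab] = tally.get(lab, 0) + 1
            sample_names.append(f"{lab}{tally[lab]}")
    rng = np.random.default_rng(seed)
    q = truth["base_mean"].to_numpy()
    lfc = truth["true_log2fc"].to_numpy()
    cols = {}
    for j, (name, lab) in enumerate(zip(sample_names, labels)):
        mu = s[j] * q * np.where(lab == exposed_label, 2.0**lfc, 1.0)
        alphas = truth["dispersion"].to_numpy()
        if np.all(alphas == alphas[0]):
            cols[name] = _nb_draw(rng, mu, float(alphas[0]))
        else:
            cols[name] = np.array(
                [_nb_draw(rng, np.array([m]), float(a))[0] for m, a in zip(mu, alphas)]
            )
    return pd.DataFrame(cols, index=pd.Index(truth.index, name="transcript_id"))


def _default_length_dist(rng: np.random.Generator, size: int) -> np.ndarray:
    return np.maximum(rng.lognormal(math.log(800), 0.7, size).astype(int), 150)


def simulate_transcripts(
    n: int,
    length_dist: Optional[Callable[[np.random.Generator, int], np.ndarray]] = None,
    seed: int = 0,
    gene_ids: Optional[Sequence[str]] = None,
) -> List[SeqRecord]:
    """Random A/C/G/T transcript sequences (lengths must be >= 100)."""
    rng = np.random.default_rng(seed)
    if n == 0:
        return []
    dist = length_dist or _default_length_dist
    lengths = np.asarray(dist(rng, n), dtype=int)
    if (lengths < 100).any():
        raise ValueError("transcript lengths must be >= 100")
    ids = list(gene_ids) if gene_ids is not None else [f"g{i:05d}" for i in range(n)]
    records = []
    for tid, length in zip(ids, lengths):
        seq = "".join(_BASES[rng.integers(0, 4, size=length)])
        records.append(SeqRecord(Seq(seq), id=tid, description=""))
    return records


def fragment_transcriptome(
    transcripts: Sequence[SeqRecord],
    model: FragmentationModel = FragmentationModel(),
    seed: int = 0,
) -> Tuple[List[SeqRecord], Dict[str, str]]:
    """Turn a clean transcript set into a redundant contig set.

    Every contig is a contiguous substring of exactly one parent
    transcript; the returned parent map is total and single-valued.
    """
    if not transcripts:
        raise ValueError("need at least one transcript")
    rng = np.random.default_rng(seed)
    contigs: List[SeqRecord] = []
    parent_map: Dict[str, str] = {}
    for rec in transcripts:
        n_copies = 2 if rng.random() < model.dup_rate else 1
        seq = str(rec.seq)
        for c in range(n_copies):
            if rng.random() < model.frag_rate:
                frac = rng.uniform(model.min_frac, model.max_frac)
                flen = max(1, int(len(seq) * frac))
                start = int(rng.integers(0, len(seq) - flen + 1))
                sub = seq[start : start + flen]
            else:
                sub = seq
            cid = f"{rec.id}.c{c}"
            contigs.append(SeqRecord(Seq(sub), id=cid, description=""))
            parent_map[cid] = rec.id
    return contigs, parent_map


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def simulate_reads(
    transcripts: Sequence[SeqRecord],
    abundances: Sequence[float],
    n_pairs: int,
    read_len: int = 60,
    qmodel: QualityModel = QualityModel(),
    seed: int = 0,
) -> List[Tuple[ReadRecord, ReadRecord]]:
    """Paired 60 bp-style reads with injected quality pathologies.

    Mates share an identifier stem with /1 and /2 suffixes; bases are
    copied from the source transcript without sequencing error (quality
    pathologies only), since alignment is not part of this pipeline.
    """
    if not transcripts:
        raise ValueError("need at least one transcript")
    lens = np.array([len(t.seq) for t in transcripts])
    if read_len > lens.min():
        raise ValueError(
            f"read_len {read_len} exceeds the shortest transcript ({lens.min()} bp)"
        )
    w = np.asarray(abundances, dtype=float)
    if (w < 0).any() or w.sum() <= 0 or len(w) != len(transcripts):
        raise ValueError("abundances must be non-negative weights, one per transcript")
    rng = np.random.default_rng(seed)
    probs = w / w.sum()
    picks = rng.choice(len(transcripts), size=n_pairs, p=probs)
    pairs = []
    for i, t_idx in enumerate(picks):
        seq = str(transcripts[t_idx].seq)
        span = min(len(seq), 2 * read_len)
        start = int(rng.integers(0, len(seq) - span + 1))
        frag = seq[start : start + span]
        mate_seqs = [frag[:read_len], _revcomp(frag[-read_len:])]
        stem = f"sim{i:07d}"
        mates = []
        for m, mseq in enumerate(mate_seqs):
            quals = np.clip(
                np.round(qmodel.mean_start_q - qmodel.decay_per_base * np.arange(read_len)),
                3,
                41,
            ).astype(int)
            if rng.random() < qmodel.dip_prob:
                pos = int(rng.integers(0, read_len))
                quals[pos] = qmodel.draw_dip_q(rng)
            if rng.random() < qmodel.b_tail_prob:
                tail = min(qmodel.draw_tail_len(rng), read_len)
                quals[read_len - tail :] = 2
            bases = np.array(list(mseq))
            n_mask = rng.random(read_len) < qmodel.n_prob
            bases[n_mask] = "N"
            mates.append(ReadRecord(f"{stem}/{m + 1}", "".join(bases), list(quals)))
        pairs.append((mates[0], mates[1]))
    return pairs


def simulate_annotation(
    parent_map: Mapping[str, str],
    description_pool: Mapping[str, str],
    hit_noise: float = 0.0,
    seed: int = 0,
    *,
    annotatable_frac: float = 1.0,
    extra_hits: int = 2,
) -> pd.DataFrame:
    """Mock tabular homology hits for a contig set.

    The top-bit-score hit of each annotatable contig carries its
    parent's description, except at rate ``hit_noise`` where a random
    other description is substituted; true-hit e-values are <= 1e-10.
    A few weaker secondary hits are added per contig.
    """
    _check_prob("hit_noise", hit_noise)
    _check_prob("annotatable_frac", annotatable_frac)
    rng = np.random.default_rng(seed)
    descs = list(dict.fromkeys(description_pool.values()))
    rows = []
    for contig, parent in parent_map.items():
        if rng.random() >= annotatable_frac:
            continue
        true_desc = description_pool[parent]
        top_desc = true_desc
        if hit_noise > 0 and rng.random() < hit_noise and len(descs) > 1:
            others = [d for d in descs if d != true_desc]
            top_desc = others[int(rng.integers(0, len(others)))]
        top_bits = float(rng.uniform(400, 900))
        hit_list = [(f"sbj_{parent}", top_desc, top_bits, 10.0 ** -rng.uniform(30, 180))]
        for e in range(int(rng.integers(0, extra_hits + 1))):
            hit_list.append(
                (
                    f"sbj_rand{int(rng.integers(0, 10**6)):06d}",
                    descs[int(rng.integers(0, len(descs)))],
                    float(rng.uniform(30, top_bits * 0.8)),
                    10.0 ** -rng.uniform(2, 30),
                )
            )
        for sbj, desc, bits, evalue in hit_list:
            rows.append(
                {
                    "qseqid": contig,
                    "sseqid": sbj,
                    "pident": float(rng.uniform(60, 100)),
                    "length": int(rng.integers(50, 500)),
                    "mismatch": int(rng.integers(0, 30)),
                    "gapopen": int(rng.integers(0, 5)),
                    "qstart": 1,
                    "qend": 100,
                    "sstart": 1,
                    "send": 100,
                    "evalue": evalue,
                    "bitscore": bits,
                    "description": desc,
                }
            )
    cols = [
        "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
        "qstart", "qend", "sstart", "send", "evalue", "bitscore", "description",
    ]
    return pd.DataFrame(rows, columns=cols)


def simulate_probe_hits(
    parent_map: Mapping[str, str],
    probes: Mapping[str, str],
    seed: int = 0,
) -> pd.DataFrame:
    """Mock probe-vs-contig hits: each probe's best hit lands on a
    contig of its source gene."""
    rng = np.random.default_rng(seed)
    by_gene: Dict[str, List[str]] = {}
    for contig, gene in parent_map.items():
        by_gene.setdefault(gene, []).append(contig)
    rows = []
    for probe, gene in probes.items():
        contigs = sorted(by_gene.get(gene, []))
        if not contigs:
            continue
        target = contigs[int(rng.integers(0, len(contigs)))]
        rows.append(
            {
                "qseqid": probe,
                "sseqid": target,
                "pident": float(rng.uniform(90, 100)),
                "length": 60,
                "mismatch": 0,
                "gapopen": 0,
                "qstart": 1,
                "qend": 60,
                "sstart": 1,
                "send": 60,
                "evalue": 10.0 ** -rng.uniform(20, 60),
                "bitscore": float(rng.uniform(100, 200)),
                "description": "",
            }
        )
    cols = [
        "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
        "qstart", "qend", "sstart", "send", "evalue", "bitscore", "description",
    ]
    return pd.DataFrame(rows, columns=cols)


def simulate_microarray(
    truth: pd.DataFrame,
    compression: float = 0.25,
    noise_sd: float = 0.1,
    range_cap: float = 3.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Microarray fold-change table with compressed dynamic range.

    ``array log2FC = clamp(compression * true_log2fc + noise,
    +/- range_cap)``; probes of truly DE genes are flagged significant
    (array power is not modelled).  One probe per gene.
    """
    if not 0.0 < compression <= 1.0:
        raise ValueError("compression must lie in (0, 1]")
    if noise_sd < 0 or range_cap <= 0:
        raise ValueError("noise_sd >= 0 and range_cap > 0 required")
    rng = np.random.default_rng(seed)
    lfc = compression * truth["true_log2fc"].to_numpy() + rng.normal(
        0.0, noise_sd, len(truth)
    )
    lfc = np.clip(lfc, -range_cap, range_cap)
    return pd.DataFrame(
        {
            "probe_id": [f"probe_{g}" for g in truth["gene_id"]],
            "gene_id": truth["gene_id"].to_numpy(),
            "log2fc": lfc,
            "significant": truth["is_de"].to_numpy(),
        }
    )


def simulate_alignments(
    gene_counts: pd.DataFrame,
    parent_map: Mapping[str, str],
    contig_lens: Mapping[str, int],
    seed: int = 0,
    read_len: int = 60,
) -> Dict[str, str]:
    """Per-sample SAM text realizing gene-level counts on contigs.

    Each gene's fragments in a sample are split among that gene's
    contigs with fixed Dirichlet weights (drawn once per gene, shared
    across samples, so contig-level means stay proportional to the gene
    means); each fragment becomes one properly paired record pair.
    Alignment placement is by construction — read positions are drawn
    uniformly, not computed by an aligner.
    """
    rng = np.random.default_rng(seed)
    by_gene: Dict[str, List[str]] = {}
    for contig, gene in parent_map.items():
        by_gene.setdefault(gene, []).append(contig)
    for gene in by_gene:
        by_gene[gene].sort()
    weights = {
        gene: rng.dirichlet(np.ones(len(contigs)) * 5.0)
        for gene, contigs in by_gene.items()
    }
    header_lines = ["@HD\tVN:1.6\tSO:unknown"]
    for contig in sorted(contig_lens):
        header_lines.append(f"@SQ\tSN:{contig}\tLN:{contig_lens[contig]}")
    header = "\n".join(header_lines) + "\n"

    sams: Dict[str, str] = {}
    counts_arr = gene_counts.to_numpy(dtype=np.int64)
    genes = list(gene_counts.index)
    for col, sample in enumerate(gene_counts.columns):
        lines: List[str] = []
        serial = 0
        for row, gene in enumerate(genes):
            n_frag = int(counts_arr[row, col])
            contigs = by_gene.get(gene)
            if not contigs or n_frag == 0:
                continue
            split = rng.multinomial(n_frag, weights[gene])
            for contig, n_c in zip(contigs, split):
                if n_c == 0:
                    continue
                clen = contig_lens[contig]
                span = min(clen, 2 * read_len)
                rlen = min(read_len, clen)
                starts = rng.integers(1, max(clen - span + 1, 1) + 1, size=n_c)
                for pos in starts:
                    pos2 = pos + span - rlen
                    qname = f"frag_{sample}_{serial:08d}"
                    serial += 1
                    lines.append(
                        f"{qname}\t99\t{contig}\t{pos}\t255\t{rlen}M\t=\t{pos2}\t{span}\t*\t*"
                    )
                    lines.append(
                        f"{qname}\t147\t{contig}\t{pos2}\t255\t{rlen}M\t=\t{pos}\t-{span}\t*\t*"
                    )
        sams[sample] = header + "\n".join(lines) + ("\n" if lines else "")
    return sams


def write_fasta(records: Iterable[SeqRecord], path) -> None:
    from Bio import SeqIO

    SeqIO.write(list(records), str(path), "fasta")


def write_paired_fastq(
    pairs: Sequence[Tuple[ReadRecord, ReadRecord]],
    path1,
    path2,
    encoding: str = "phred33",
) -> None:
    with open(path1, "w") as h1, open(path2, "w") as h2:
        for r1, r2 in pairs:
            h1.write(f"@{r1.id}\n{r1.bases}\n+\n{encode_quality(r1.quals, encoding)}\n")
            h2.write(f"@{r2.id}\n{r2.bases}\n+\n{encode_quality(r2.quals, encoding)}\n")


def write_sam(sam_text: str, path) -> None:
    with open(path, "w") as h:
        h.write(sam_text)
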