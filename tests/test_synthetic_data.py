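"""Generators: truth tables, NB counts, sequences, reads, hit tables,
microarray emulation — including the configured-rate guarantees the
downstream tests rely on."""

import io

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from denovodge import synthetic_data as sd
from denovodge.quantify import build_matrix, count_sample
from denovodge.read_filter import FilterConfig, encode_quality, filter_read

DESIGN_3V2 = ["exposed"] * 3 + ["reference"] * 2


class TestSimulateTruth:
    def test_null_truth(self):
        t = sd.simulate_truth(100, 0.0, seed=1)
        assert (t["true_log2fc"] == 0).all() and not t["is_de"].any()

    def test_forced_de_count(self):
        t = sd.simulate_truth(100, 0.2, seed=1)
        assert t["is_de"].sum() == 20

    def test_determinism(self):
        a = sd.simulate_truth(50, 0.5, seed=9)
        b = sd.simulate_truth(50, 0.5, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_invariants(self):
        t = sd.simulate_truth(500, 0.3, seed=2)
        assert ((t["true_log2fc"] != 0) == t["is_de"]).all()
        assert (t["base_mean"] > 0).all()
        assert (t.loc[t["is_de"], "true_log2fc"].abs() >= 0.5).all()
        # symmetric sign mix
        signs = np.sign(t.loc[t["is_de"], "true_log2fc"])
        assert 0.3 < (signs > 0).mean() < 0.7

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            sd.simulate_truth(10, float("nan"))
        with pytest.raises(ValueError):
            sd.simulate_truth(10, 0.1, lfc_sd=float("inf"))


class TestSimulateCounts:
    def test_poisson_variance_mean_ratio(self):
        # dispersion 0 degenerates to Poisson: per-gene VMR ~ 1
        truth = sd.simulate_truth(
            5000, 0.0, dispersion=0.0, seed=3, base_mean_median=500, base_mean_log_sd=0.1
        )
        mat = sd.simulate_counts(truth, [1.0] * 6, ["exposed"] * 3 + ["reference"] * 3, seed=4)
        vmr = mat.var(axis=1, ddof=1) / mat.mean(axis=1)
        # mean VMR over 5000 genes has SE ~ sqrt(2/5)/sqrt(5000) ~ 0.009
        assert abs(vmr.mean() - 1.0) < 0.03

    def test_fold_change_recovered_in_means(self):
        truth = sd.simulate_truth(2000, 0.0, dispersion=0.0, seed=5, base_mean_median=500,
                                  base_mean_log_sd=0.0)
        truth["true_log2fc"] = 2.0
        mat = sd.simulate_counts(truth, [1.0] * 4, ["exposed"] * 2 + ["reference"] * 2, seed=6)
        ratio = mat.iloc[:, :2].mean(axis=1).sum() / mat.iloc[:, 2:].mean(axis=1).sum()
        assert ratio == pytest.approx(4.0, rel=0.02)

    def test_null_conditions_exchangeable(self):
        truth = sd.simulate_truth(5000, 0.0, dispersion=0.1, seed=7)
        mat = sd.simulate_counts(truth, [1.0] * 4, ["exposed"] * 2 + ["reference"] * 2, seed=8)
        diff = mat.iloc[:, :2].mean(axis=1) - mat.iloc[:, 2:].mean(axis=1)
        # centred at zero within a generous CI
        se = diff.std(ddof=1) / np.sqrt(len(diff))
        assert abs(diff.mean()) < 4 * se

    def test_negative_size_factor_rejected(self):
        truth = sd.simulate_truth(10, 0.0, seed=1)
        with pytest.raises(ValueError):
            sd.simulate_counts(truth, [1.0, -1.0], ["exposed", "reference"])


class TestSequences:
    def test_empty_set(self):
        assert sd.simulate_transcripts(0) == []

    def test_lengths_from_dist(self):
        recs = sd.simulate_transcripts(10, length_dist=lambda rng, n: np.full(n, 321), seed=1)
        assert len(recs) == 10 and all(len(r.seq) == 321 for r in recs)

    def test_deterministic_fasta_bytes(self, tmp_path):
        for name in ("a.fasta", "b.fasta"):
            sd.write_fasta(sd.simulate_transcripts(5, seed=42), tmp_path / name)
        assert (tmp_path / "a.fasta").read_bytes() == (tmp_path / "b.fasta").read_bytes()

    def test_short_lengths_rejected(self):
        with pytest.raises(ValueError):
            sd.simulate_transcripts(3, length_dist=lambda rng, n: np.full(n, 50))


class TestFragmentation:
    def test_zero_rates_identity(self):
        transcripts = sd.simulate_transcripts(5, seed=1)
        contigs, parents = sd.fragment_transcriptome(
            transcripts, sd.FragmentationModel(dup_rate=0, frag_rate=0), seed=2
        )
        assert [str(c.seq) for c in contigs] == [str(t.seq) for t in transcripts]
        assert set(parents.values()) == {t.id for t in transcripts}

    def test_half_fragments(self):
        transcripts = sd.simulate_transcripts(20, seed=3)
        contigs, parents = sd.fragment_transcriptome(
            transcripts,
            sd.FragmentationModel(dup_rate=0, frag_rate=1, min_frac=0.5, max_frac=0.5),
            seed=4,
        )
        by_id = {t.id: len(t.seq) for t in transcripts}
        for c in contigs:
            assert len(c.seq) == by_id[parents[c.id]] // 2

    def test_parent_map_total_and_substring(self):
        transcripts = sd.simulate_transcripts(30, seed=5)
        contigs, parents = sd.fragment_transcriptome(transcripts, seed=6)
        seqs = {t.id: str(t.seq) for t in transcripts}
        assert set(parents) == {c.id for c in contigs}
        for c in contigs:
            assert str(c.seq) in seqs[parents[c.id]]


class TestSimulateReads:
    def test_clean_model_passes_filter_entirely(self):
        transcripts = sd.simulate_transcripts(4, seed=1)
        qm = sd.QualityModel(n_prob=0, b_tail_prob=0, dip_prob=0, mean_start_q=38)
        pairs = sd.simulate_reads(transcripts, [1] * 4, 500, qmodel=qm, seed=2)
        assert all(
            filter_read(r).passed for pair in pairs for r in pair
        )

    def test_all_n_rejected(self):
        transcripts = sd.simulate_transcripts(2, seed=1)
        qm = sd.QualityModel(n_prob=1.0, b_tail_prob=0, dip_prob=0)
        pairs = sd.simulate_reads(transcripts, [1, 1], 50, qmodel=qm, seed=3)
        assert all(
            filter_read(r).reason == "uncalled" for pair in pairs for r in pair
        )

    def test_q2_encodes_as_B_in_phred64(self):
        transcripts = sd.simulate_transcripts(2, seed=1)
        qm = sd.QualityModel(n_prob=0, b_tail_prob=1.0, dip_prob=0)
        pairs = sd.simulate_reads(transcripts, [1, 1], 20, read_len=60, qmodel=qm, seed=4)
        r1 = pairs[0][0]
        assert r1.quals[-1] == 2
        assert encode_quality(r1.quals, "phred64").endswith("B")

    def test_pathology_rates_within_binomial_tolerance(self):
        transcripts = sd.simulate_transcripts(5, seed=1)
        qm = sd.QualityModel(n_prob=0.01, b_tail_prob=0.15, dip_prob=0)
        n_pairs = 2000
        pairs = sd.simulate_reads(transcripts, [1] * 5, n_pairs, qmodel=qm, seed=5)
        reads = [r for pair in pairs for r in pair]
        n_bases = sum(len(r.bases) for r in reads)
        n_count = sum(r.bases.count("N") for r in reads)
        for observed, n, p in (
            (n_count, n_bases, qm.n_prob),
            (sum(r.quals[-1] == 2 for r in reads), len(reads), qm.b_tail_prob),
        ):
            se = np.sqrt(n * p * (1 - p))
            assert abs(observed - n * p) < 3 * se

    def test_read_longer_than_shortest_transcript_rejected(self):
        transcripts = sd.simulate_transcripts(2, length_dist=lambda r, n: np.full(n, 100), seed=1)
        with pytest.raises(ValueError, match="shortest"):
            sd.simulate_reads(transcripts, [1, 1], 10, read_len=120)

    def test_determinism_and_mate_sync(self, tmp_path):
        transcripts = sd.simulate_transcripts(3, seed=1)
        for name in ("x", "y"):
            pairs = sd.simulate_reads(transcripts, [1] * 3, 100, seed=77)
            sd.write_paired_fastq(pairs, tmp_path / f"{name}_1.fq", tmp_path / f"{name}_2.fq")
        assert (tmp_path / "x_1.fq").read_bytes() == (tmp_path / "y_1.fq").read_bytes()
        pairs = sd.simulate_reads(transcripts, [1] * 3, 100, seed=77)
        assert all(r1.id[:-2] == r2.id[:-2] for r1, r2 in pairs)


class TestAnnotationAndArray:
    def test_empty_parent_map(self):
        assert sd.simulate_annotation({}, {}).empty

    def test_bitscores_positive_and_true_evalues_pass(self):
        transcripts = sd.simulate_transcripts(10, seed=1)
        contigs, parents = sd.fragment_transcriptome(transcripts, seed=2)
        pool = {t.id: f"protein {t.id}" for t in transcripts}
        hits = sd.simulate_annotation(parents, pool, seed=3)
        assert (hits["bitscore"] > 0).all()
        top = hits.sort_values("bitscore", ascending=False).groupby("qseqid").head(1)
        assert (top["evalue"] <= 1e-10).all()
        assert (top["description"] == top["qseqid"].map(
            lambda c: pool[parents[c]])).all()

    def test_array_identity_without_noise(self):
        truth = sd.simulate_truth(100, 0.5, seed=1)
        arr = sd.simulate_microarray(truth, compression=1.0, noise_sd=0.0, range_cap=1e9)
        assert np.allclose(arr["log2fc"], truth["true_log2fc"])

    def test_array_range_cap(self):
        truth = sd.simulate_truth(200, 0.5, lfc_sd=3.0, seed=2)
        arr = sd.simulate_microarray(truth, compression=1.0, noise_sd=0.5, range_cap=3.5)
        assert arr["log2fc"].abs().max() <= 3.5

    def test_array_compression_slope(self):
        truth = sd.simulate_truth(300, 0.5, seed=3)
        arr = sd.simulate_microarray(truth, compression=0.5, noise_sd=0.0, range_cap=1e9)
        slope = sps.linregress(truth["true_log2fc"], arr["log2fc"]).slope
        assert slope == pytest.approx(0.5, abs=1e-9)


class TestSimulateAlignments:
    def test_counts_recovered_exactly(self, tmp_path):
        truth = sd.simulate_truth(30, 0.2, seed=1, base_mean_median=50)
        transcripts = sd.simulate_transcripts(30, seed=2, gene_ids=list(truth["gene_id"]))
        contigs, parents = sd.fragment_transcriptome(transcripts, seed=3)
        lens = {c.id: len(c.seq) for c in contigs}
        gene_counts = sd.simulate_counts(truth, [1.0] * 5, DESIGN_3V2, seed=4)
        sams = sd.simulate_alignments(gene_counts, parents, lens, seed=5)
        per_sample = {}
        for sample, text in sams.items():
            path = tmp_path / f"{sample}.sam"
            sd.write_sam(text, path)
            per_sample[sample] = count_sample(path, lens, unit="fragment")
        mat = build_matrix(per_sample, list(gene_counts.columns))
        # summing contig counts per parent gene reproduces the gene counts
        regrouped = mat.groupby([parents[c] for c in mat.index]).sum()
        pd.testing.assert_frame_equal(
            regrouped.sort_index(), gene_counts.sort_index(), check_names=False
        )
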