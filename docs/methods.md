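# Methods

This note documents the models, the conventions adopted where the
classic GA-era analysis leaves details open, the synthetic-data
generator's assumptions, and the numerical choices. Nothing here
states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Read filtration

A read is processed in a fixed rule order:

1. **Uncalled bases.** Any base outside {A, C, G, T} rejects the whole
   read.
2. **Q2 truncation.** Quality 2 is the GA-era reliability flag
   (encoded 'B' in phred+64): everything downstream of its first
   occurrence is untrustworthy. The flagged position itself is also
   removed — the flag marks the base as unreliable, so keeping it
   would be inconsistent; removal is the conservative reading. The
   rule keys on the decoded score, not the glyph, so phred+33 input
   ('#') behaves identically.
3. **Splitting.** Position *p* fails when `q[p] <= 10` or when the
   mean of `q[p-1..p+1]` is `<= 20`. At the read termini the window
   mean is taken over the neighbours that exist (two values instead of
   three); the window rule is otherwise undefined there.
4. **Selection.** The longest maximal run of passing positions is
   kept if it is at least 49 bp; ties keep the 5'-most run so the
   outcome is deterministic.

Paired-end bookkeeping: when exactly one mate survives it moves to a
single-end stream; the counters satisfy
`2*pairs_out + singles_out + rejected_uncalled + rejected_short =
reads_in` exactly, which the implementation asserts on every run.

The filter is validated against an independent brute-force oracle
that enumerates all contiguous substrings of a read and keeps the
longest all-passing one; the two agree on thousands of random reads
up to 80 bp (hypothesis property plus a fixed 1,000-read sweep).

## Assembly statistics

N50 uses the `>=` half-total convention on the descending sort, so it
is always a member length; ties resolve naturally through the scan.
The k-mer selection rule operationalizes the visual "largest k on the
N50 plateau before the dip": the plateau is the maximal contiguous run
containing the argmax whose N50 stays within a tolerance (default 5%)
of the maximum, and the chosen k is its right edge. The original
choice was made by eye, so the tolerance is an explicit parameter
rather than a claim of fidelity. Volcano-plot length bins read
"between 300 and 3,000 bp" as inclusive of both endpoints.

## Quantification

Counting units: `read` (each mapped record adds 1) or `fragment` (a
proper pair with both mates on one contig adds 1; any other mapped
read adds 1 to its own contig). Mates on different contigs count as
two single reads rather than half each — the NB test needs integer
counts. Multi-mapper assignment is the aligner's responsibility; the
counter counts each record once, so counting is deterministic and
order-independent. The low-count rule drops contigs with fewer than
10 mapped reads **pooled over all samples**; a per-sample variant
would be a different filter, and the pooled reading matches a single
global surviving-contig count. Externally added reference sequences
(e.g. cDNAs for genes that assembled poorly) are merged with
provenance labels and collision-renamed with an `_ext` suffix.

## Negative-binomial differential expression

Counts K_ij ~ NB(mean s_j q_i, variance mu + alpha*mu^2), with a
single quadratic overdispersion alpha shared across genes.

**Size factors** are the median over all-nonzero genes of
k_ij / geomean_v(k_iv). When no gene is nonzero in every sample the
estimator is undefined and the error message suggests a
pseudo-reference fallback rather than silently switching.

**Dispersion.** Within each condition with >= 2 replicates, the
unbiased variance w of normalized counts estimates
`q * mean(1/s_j) + alpha * q^2` (the first term is the Poisson shot
noise expressed on the normalized scale — with unit size factors it
reduces to the plain `variance - mean` residual). alpha is fitted by
least squares of `w - shot` against `q^2`, constrained to alpha >= 0,
**iteratively reweighted** by the sampling variance of w
(Var(w) ≈ 2σ⁴/df with σ² = shot + alpha·q²). Plain (unweighted)
least squares is equivalent to weighting genes by q⁴ and is therefore
dominated by the handful of most-expressed genes; at a few hundred
genes this makes alpha-hat swing by an order of magnitude between
datasets, which in turn makes the exact test badly anti-conservative.
Four reweighting iterations from the OLS start are ample. The
estimator recovers alpha = 0.2 within ±0.05 at 5,000 genes and gives
~0 on Poisson data; the per-gene diagnostics are retained on the fit
object. A local-regression mean–variance fit is a possible extension
hook; the parametric form is deterministic and stable at these sizes.

**Exact test.** For one gene, let K_A and K_B be the condition
totals, q̂ = (K_A+K_B)/(S_A+S_B) the pooled (size-factor-weighted)
expression, and model each total as NB with mean q̂·S and variance
`mu + alpha·q̂²·Σ s_j²` (the variance of a sum of independent NB
mates, matched by moments). Conditioning on T = K_A + K_B, the
two-sided p-value sums P(a, T−a) over all splits at most as probable
as the observed one, normalized by the sum over all splits. With
alpha = 0 this reduces exactly to the minimum-likelihood two-sided
binomial test with success probability S_A/(S_A+S_B), which is the
cross-check oracle in the tests. A zero gene total returns p = 1.
Numerics: pmfs are evaluated in log space and combined with
logsumexp; "at most as probable" uses a 1e-8 log-space tolerance so
floating-point ties (e.g. the symmetric balanced case) are counted.

**Reporting conventions.** log2FC = log2(mean_exp/mean_ref) of
normalized condition means; when exactly one condition mean is zero
the value is the sentinel ±0.5 (in place of ±infinity) with
`one_condition_flag` set, stored alongside the flag so downstream
consumers can exclude sentinels rather than inheriting them silently.
Significance is the **raw** p-value against the threshold (default
0.01) with no multiple-testing adjustment — the faithful but liberal
headline convention of this analysis style; users wanting FDR control
should adjust `pval` themselves.

**Clustering.** Sample distances are computed on log2(normalized
count + 1) profiles, with 1 − Pearson (default) or Euclidean metrics
and complete-linkage agglomeration for the leaf order.

## Annotation grouping

Hits are filtered at e-value <= 1e-10 and at most 10 per query by
descending bit score; the best hit breaks ties by lower e-value, then
lexicographic subject id. Descriptions are case-folded and
whitespace-collapsed before uniqueness — without some normalization
the "unique description" count is unstable; no claim is made that
this matches any particular historical normalization. A description
whose transcripts are significant in both directions appears in both
sets (exposed via `conflicts`) rather than being silently resolved.
Significant transcripts with no surviving hit are tallied, with a
sub-tally of those longer than 1 kb.

## Microarray concordance

Each probe is matched to the contig of its best surviving hit
(many probes may share a contig; matching is per-probe). Pearson r is
reported over all retained matches and over the doubly significant
subset; the least-squares line regresses **array** log2FC on
**RNA-Seq** log2FC on the doubly significant subset, so with a
noise-free array generated at compression c the slope estimates c.
Sentinel (one-condition) RNA-Seq fold changes are excluded by default
— a finite array ratio against an artificial ±0.5 carries no
magnitude information — and a flag restores them for sensitivity
analysis.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *statistical* structure the pipeline
assumes, not the biology or the sequencing chemistry:

- **Truth.** Expected levels are log-normal (an explicit stand-in —
  the real abundance distribution of these libraries is unknown);
  exactly `round(n_genes * frac_de)` genes are DE with
  log2FC = sign·(min + |N(0, sd)|), a symmetric two-component
  distribution with a minimum magnitude so that no true effect is
  undetectably small and power statements stay meaningful.
- **Counts.** NB with variance mu + alpha·mu², dispersion 0 giving
  Poisson — exactly the DE module's model, by design.
- **Reads.** 60 bp pairs drawn uniformly along transcripts with
  *quality* pathologies only (Q2 tails at rate 0.1 with geometric
  mean length 10, uncalled bases at 2e-3 per base, one low-quality
  dip per read at rate 0.1, start quality 35 decaying 0.1/base).
  These defaults give an overall pass rate of ~80%, at the low end of
  the 81–94% range typical of GA-era libraries. Base-call errors,
  PCR duplication and strand-specific protocols are *not* modelled:
  alignment is out of scope here, so erroneous bases would add
  nothing testable.
- **Assembly stand-in.** Each transcript yields an extra alternative
  contig with probability 0.3 and each contig is independently
  replaced by a contiguous sub-fragment (30–90% of the parent) with
  probability 0.4 — redundancy and fragmentation without running an
  assembler.
- **Alignments.** SAM records are placed by construction (uniform
  positions, proper pairs), realizing per-gene NB counts split among
  the gene's contigs with Dirichlet weights fixed across samples, so
  contig-level means stay proportional to gene means.
- **Annotation / array.** The top hit of each contig carries its
  parent's description (corrupted at a configurable `hit_noise`
  rate); array log2FC = clamp(compression·truth + noise, ±cap),
  emulating the compressed dynamic range of hybridization platforms.

Consequently, passing tests demonstrate correctness of the
*computational* stages under the model's own assumptions; they say
nothing about aligner behaviour, assembly quality on real data, or
biological interpretation.

## End-to-end study sizing

The default `StudyConfig` is a desk-scale 3-exposed vs
2-pooled-reference contrast: 120 genes, 20% DE, alpha = 0.1, size
factors 0.8–1.2, base means log-normal (median 400, floor 250), true
|log2FC| in [3.5, ~4.7], 3,000 read pairs, 60 bp.

The effect floor comes from a power analysis, not taste: with
alpha = 0.1 and five replicates the log2FC estimator has standard
deviation ≈ sqrt(alpha·(1/3 + 1/2))/ln 2 ≈ 0.42, so exact
reconstruction of the true DE gene set — every true gene called, no
null gene called — needs the weakest true effect several estimator-SDs
above the largest null excursion, i.e. |log2FC| ≳ 0.42·(z_strict +
z_extreme) ≈ 3.5. Reconstruction is scored at a strict P < 1e-5:
under a raw-p rule at the headline 0.01, false positives among
hundreds of null contigs are expected *by construction*, so set
identity is only meaningful at a threshold where the null contributes
essentially no calls. Headline significance reporting everywhere else
stays at P < 0.01.

Problem sizes elsewhere: type-I calibration on a 2,000-gene null,
dispersion recovery on 5,000 genes, power/direction at 1,000 genes
(30% DE at |log2FC| = 2, base mean >= 100), filter invariants on
10,000 pathological reads, N50 oracle on 1,000 random sets. The full
suite runs in well under a minute on one CPU.

## Known limitations

- The shared-alpha NB model cannot express per-gene dispersion;
  genuinely heteroskedastic data will be mis-calibrated in the tails.
- The exact test is discrete and therefore conservative at low
  counts; the null significant fraction sits slightly below nominal
  for weakly expressed genes.
- Raw-p thresholding does not control FDR.
- The plateau rule for k selection is an operationalization of a
  visual judgement and has a free tolerance parameter.
- Description-based grouping inherits every quirk of the hit
  descriptions; isoform-suffix deduplication is limited to case and
  whitespace normalization.
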