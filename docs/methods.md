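# Methods

## The problem and the signal

A typical (non-differential) strand-specific RNA-seq experiment, mapped at
single-nucleotide resolution, carries enough information to annotate the
*structure* of a bacterial transcriptome: where primary transcripts start,
how long their 5′-UTRs are, which genes are co-transcribed, and where the
automated structural annotation of start codons is wrong. `txarch`
formalizes the visual criteria a curator applies to such maps into
deterministic, parameterized rules so the analysis is reproducible and
testable. It cannot distinguish primary 5′ ends from processed 5′ ends —
neither can the underlying library type — so "TSS" here means the 5′ end of
an abundant transcript supported by a sharp coverage step.

## TSS calling

Per library and strand, position *i* is a candidate when

* depth(i) ≥ `d_min` (default 10 reads), and
* (depth(i) + ψ) / (mean depth over the `w` bases 5′ of *i* + ψ) ≥ `r_min`
  (defaults w = 5 nt, ψ = 1, r_min = 5).

ψ keeps the ratio finite over silent upstream regions and biases against
calling steps out of near-zero noise. A candidate must appear at the
*identical* coordinate in ≥ `m_min` libraries (default 2 of 6; the replicate
concordance demanded before trusting a step). The reported step score pools
the supporting libraries: (mean depth + ψ) / (mean upstream baseline + ψ),
which for concordant replicates equals the per-library score and is invariant
to the number of supporting libraries.

Candidates are assigned to genes through a search window from `u_max`
(default 500 nt) upstream of the annotated start codon to `d_max` (default
300 nt, capped at half the gene length) into the CDS — the downstream reach
is what makes mis-annotated (negative-UTR) starts discoverable. When
adjacent genes' windows overlap, a candidate belongs to the gene whose start
codon it is nearest to in absolute signed-UTR distance. Per gene, the single
candidate with the highest pooled score wins; ties break to the most
upstream position (the 5′-most plausible primary end). Candidates in no
window are kept as orphans in a side table, never silently dropped.

Degenerate inputs: positions within `w` of the genome edge use the truncated
upstream window (empty ⇒ baseline 0); a uniform ramp has no position whose
ratio reaches `r_min`, so monotone coverage gradients are never called.

## 5′-UTR classes and re-annotation

Signed UTR = (start codon − TSS) in gene sense. Classes: negative (< 0),
leaderless (0–9 nt), short (10–50), mid (51–100), long (≥ 101). The
leaderless boundary is "< 10 nt" with the 10 nt value itself falling in
"short"; the boundary is configurable (`leaderless_max`) because the
published binnings in this field are ambiguous about length exactly 10.

A negative-UTR gene is proposed for correction by reading the 3 nt at its
TSS (reverse-complemented on −): status `corrected` iff the codon is ATG or
GTG **and** the offset is ≡ 0 (mod 3). Both conditions follow the
field's practice: AUG/GUG at the TSS suffices for leaderless initiation in
mycobacteria, and an in-frame offset means the corrected ORF is a suffix of
the annotated one, so no internal-stop check is needed. TTG — a genuine but
rarer bacterial start — is reported as `unresolved` with reason
`codon:TTG`, never auto-corrected. A TSS within 3 nt of the genome edge is
`unresolved:edge`.

## Operon and sub-operon calling

Adjacent genes join into one transcription unit when (a) same strand,
(b) every intergenic base has pooled depth ≥ `c_min` (default 1 — the
weakest reading of "the transcript covers the gap"; abutting/overlapping
genes join trivially), and (c) max/min phase RPKM < `ratio_max` (default 2,
strict). The ratio uses plain RPKM with `epsilon` (default 0.1) clamping
only the denominator, so the 2-fold boundary is exact; a pair with both
RPKMs below `epsilon` never joins (a covered gap between two silent genes is
no evidence of co-transcription). Joins are evaluated per phase on
replicate-pooled coverage; final units are maximal runs of pairs joined in
*any* phase, with per-phase support recorded — condition-dependent operon
structure is expected, and a union preserves all evidence without inventing
an intersection rule.

A non-5′ member gene with its own called TSS marks a sub-operon. Against a
reference operon set, each multi-gene unit gets exactly one of five labels,
with `alternative` (internal TSS present) checked first, then the reference
operon of maximal Jaccard overlap: equal set ⇒ `confirmed`, reference ⊂ unit
⇒ `extended`, unit ⊂ reference ⇒ `dismissed`, no overlap ⇒ `new`. Non-nested
partial overlaps are not a published category; they are labeled `dismissed`
with an explicit `crossing_flag` rather than given a sixth label.
Monocistrons are labeled `dismissed` only when the reference embeds the gene
in a multi-gene operon, else left unlabeled.

## Quantification

Counts are recovered from coverage as Σdepth over the gene body / read
length, rounded half-up — equivalent to fractional read assignment at
uniform read length. RPKM = count·10⁹/(length·total mapped). Replicates
within a phase are pooled (counts summed) before contrasts; the analysis is
phase-level by design.

Differential expression uses an exact two-library binomial test: count_B
against n = count_A + count_B with success probability
total_B/(total_A+total_B), BH-corrected; DEG ⇔ |log2FC| ≥ 1 and FDR < 0.001.
This is the self-contained analogue of the random-sampling model behind
two-library DE tools; the thresholds, not the test family, are the contract.
Fold changes use an ε = 0.5 pseudocount so zero counts stay finite. Note
that an exact count test cannot be invariant to scaling counts and totals by
a common factor — power grows with depth — so the tested guarantees are:
gene-order invariance (exact), preservation of fold changes of expressed
genes, and preservation of positive calls under up-scaling.

The Wilcoxon rank-sum comparison of phase RPKM vectors computes exact
two-sided p by full enumeration of labelings when n ≤ 12 without ties
(symmetric-tail definition: all labelings whose min(U, n₁n₂−U) is at most
the observed one), else a normal approximation with midranks, tie correction
and continuity correction. Enrichment is the hypergeometric upper tail with
rich factor = DEGs in category / category size in background, BH-corrected
across categories and sorted by q.

## −10 motif scan

Fixed-pattern TANNNT, not de-novo discovery. The spacer counts bases
strictly between the motif's 3′ base and the TSS and must fall in 7–12 nt
(both the window and the anchoring convention are configurable and recorded
in output headers, because "x bp upstream" is ambiguous in prose). On the −
strand the pattern is matched on the reverse complement.

## What the synthetic generator emulates — and what it does not

`generate_genome` tiles transcription units (size distribution
1/2/3/4 genes at 0.55/0.20/0.15/0.10) on both strands, gene lengths
300–900 nt, intra-unit gaps 5–40 nt (covered by the transcript), inter-unit
gaps 150–400 nt (background only). Per-unit mean depth is log-normal
(μ=4.0, σ=0.6 on the log scale, i.e. median ≈ 55 reads/base) floored at
30 reads/base — the floor makes noiseless recovery a property of the method
rather than of draw luck, and represents the analysis being restricted to
expressed transcripts, as any TSS map implicitly is. 45% of TSS-bearing
genes are leaderless (UTR exactly 0; the all-leaderless limit must coincide
with TSS = start codon), leaded UTRs are uniform 15–80 nt,
round(0.07·n_genes) genes are mis-annotated with the annotated start moved
upstream by 3k nt (k = 1..8) so the pipeline sees a negative UTR, and a
TANNNT is planted 7–12 nt upstream of 70% of TSSs. All planted true starts
are ATG (70%) or GTG (30%).

Coverage (`simulate_coverage`) emulates 3 growth phases × 2 replicates.
Per-(unit, phase) abundance multiplies a log-normal factor (σ=0.4) onto the
unit's base abundance — this is what makes phase contrasts produce DEGs.
Depth is exact means in noiseless mode; otherwise negative-binomial per base
(dispersion size 10) over a Poisson background (mean 0.1), replicates drawn
independently. An optional linear 5′→3′ taper exists and defaults to off.
All randomness derives from one integer seed through spawned
`SeedSequence`s (one stream per library).

Units given an internal TSS (30% of multi-gene units) are
*condition-dependent*: transcribed from the primary TSS in the first two
phases and only from the internal TSS (a suffix transcript) in the last.
This is deliberate — if both transcripts were active additively in one
library, the internal step (ratio ≥ 5) and the operon join rule (ratio < 2)
would be mutually exclusive; stimulus-dependent sub-operon activity is also
the biological reading of "alternatively transcribed from its own TSS". The
union-across-phases join rule then recovers the full planted unit while the
suffix-only phase exposes the internal TSS cleanly.

Not emulated: read-level artifacts (the generator produces depth, not
FASTQ), sequence-composition bias, rRNA contamination, transcription
termination read-through, antisense transcription, and the heavy-tailed
positional unevenness of real libraries. Passing recovery tests therefore
shows the rules are implemented correctly and are mutually consistent — not
that the default thresholds are optimal on any particular real dataset.

## Problem sizes and determinism of the shipped checks

The test suite and `scripts/acceptance.py` use 60-gene genomes
(≈ 45–50 kb), 10 seeds for noiseless recovery and 20 for noisy recovery —
sizes at which every planted structure class appears many times per seed
while a full run stays in seconds. Noiseless recovery is asserted at 100%
(exact TSS coordinates, exact unit membership, all leaderless flags, all
planted mis-annotations corrected to the true start, zero false proposals);
noisy recovery at ≥ 95% of planted TSSs within ±1 nt. Brute-force oracles
(full labeling enumeration for the rank-sum test, exhaustive draw
enumeration for the hypergeometric tail, naive sweeps for motif scan and
per-base counting, a from-scratch set-relation classifier for the five
groups) are kept independent of the implementation paths they check.

## Known limitations

Single-contig genomes only. One TSS per gene — secondary promoters of the
same gene are not modeled (orphan candidates are retained but unclassified).
Phase-level (pooled-replicate) DE only; no dispersion-aware replicate test.
The operon caller trusts the annotation's gene order and does not call 3′
ends. The motif scan reports presence within a fixed spacer window, not a
position weight matrix score.
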