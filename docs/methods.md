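# Methods

## Scope and model of the data

`bewindow` quantifies the outcomes of CRISPR base editing from paired-end
amplicon deep sequencing.  A base editor (BE) is a Cas9 nickase fused to a
deaminase: a cytidine base editor (CBE) converts C•G to T•A, an adenine base
editor (ABE) converts A•T to G•C.  Editing is position-dependent along the
20-nt protospacer (positions numbered 1–20 five-prime to three-prime on the
protospacer strand, PAM trinucleotide at positions 21–23): canonical CBEs
edit efficiently at positions 4–8 and ABE7.10 at 4–7, with residual
"out-of-window" (bystander) activity elsewhere.  The package measures

1. per-position intended-conversion frequencies f(p),
2. the per-position inhibition rate when an editor-attenuating agent
   (e.g. an anti-CRISPR peptide) is added,

       IR(p) = 1 − f_treated(p) / f_control(p),

3. the window-focusing contrast: selectivity fold =
   mean IR(out-of-window) / mean IR(on-target), with a two-tailed
   equal-variance Student's t test between the two groups of IR values,
4. indel frequency (reads with ≥1 inserted/deleted base intersecting the
   protospacer, over all accepted reads), and
5. allele-level outcomes: each fully observed protospacer sequence is
   classified as `perfect` (exactly the intended conversions, nothing
   else), `unedited`, `imperfect_edit`, or `indel_allele`, and conditions
   are compared by perfect-of-total and perfect-of-edited fractions.

## Pipeline stages and the choices inside them

**Consensus merging.**  R2 is reverse-complemented and the best ungapped
overlap against R1 is taken over all offsets; a pair merges when the
overlap is ≥ `min_overlap` (default 11 bases) and its mismatch fraction is
≤ `max_mismatch_frac` (default 0.1 — the overlap length floor is the
stated analysis rule; the mismatch tolerance is a permissive default in
line with common merger behaviour and is configurable).  At agreeing
columns the consensus quality is the higher Phred capped at 41; at
disagreeing columns the higher-quality base wins and the consensus quality
is the difference of the two scores.  Ties between equally scoring offsets
prefer the longer overlap, then the smaller shift.  Unmerged pairs are
excluded downstream.

**Targeted alignment.**  Amplicon data are single-locus, so genome mapping
is replaced by pairwise alignment of each consensus read to the known
amplicon: global in the read with free end gaps in the amplicon, affine
gap scoring with match +2, mismatch −4, gap open −6, gap extend −1 (a gap
of length k costs 6 + k), both orientations tried and the better kept.
These are BWA-MEM-like values so indel calls remain comparable with
mapper-based pipelines.  The backend is Biopython's `PairwiseAligner`;
the test suite checks its scores against an independent Gotoh dynamic
programme on random pairs.  Reads with identity (matches / read length)
below `min_identity` (default 0.7) are rejected; this is the single-locus
analog of a minimum mapping quality, which is a multi-mapping concept with
no direct counterpart here.

**Counting.**  Base calls with Phred < `min_base_qual` (default 30) and
ambiguous bases are masked per position; deletions spanning a position are
counted separately; every count is complemented into the protospacer-strand
frame.  Insertions are attributed to the gap immediately three-prime of a
position on the protospacer strand (a deterministic bookkeeping convention;
placement within homopolymers is aligner-dependent and inherently
ambiguous).  Frequencies use position-specific denominators
(total − masked − deleted at that position) because masking varies by
position; a zero denominator yields "undefined", never 0.  The matrix
retains all base counts, so conversion can be recomputed under alternative
denominator conventions if needed.

**Inhibition metrics.**  IR(p) is computed only where the control frequency
is ≥ `min_control_freq` (default 0.005): ratios against near-zero controls
are dominated by sampling noise.  Reported IR is clamped to [0, 1]
(heat-map semantics); the raw value is retained.  IR is computed per
matched control/treated replicate pair, then replicate (and optionally
site) values are pooled into the two window groups.  The selectivity fold
is the ratio of pooled group means; the group test is the equal-variance
Student's t (two-tailed), with Welch available behind a flag.  Degenerate
zero-variance groups return t = 0, p = 1 when means coincide.

**Allele calling.**  The quantification region defaults to protospacer
positions 1–20 (PAM and flanks excluded, configurable).  Reads not fully
covering the region, or with any masked base inside it, are dropped from
allele calling (and counted) because allele identity requires full
observation; they still contribute to the per-position matrix.  A
non-intended product at an intended position (e.g. C→G at position 4) is
`imperfect_edit`, not `perfect`.  Alleles rarer than `min_allele_count`
can be pooled into an "other" bin; summary fractions are computed before
pooling.

**QC.**  Samples whose accepted-read total is below `min_reads` are
excluded with a logged reason.  The default is 0 (disabled): the published
description of the read-count exclusion threshold for this assay is
implausible as stated, so no default is inherited and the threshold is
left to the user.

## The simulator

The generator (`bewindow.simulate`) is the oracle for every stage.  One
sample is: `coverage` reads drawn from an allele distribution defined by
per-position Bernoulli conversion probabilities over the editable
positions (window-shaped by default: peaks 0.4–0.5 in the on-target
window, tails ≤ 0.15 outside, matching the magnitude of efficient editing
at a well-edited locus), an optional treated condition that multiplies
each position's probability by (1 − IR(p)), per-read indels (default off;
presets use 0.5–1%, uniform position in the protospacer, lengths 1–3),
and paired 100-nt reads over the 120-nt amplicon with independent per-base
miscalls (default 0.2%) and Phred scores drawn from a truncated normal
(mean 35, sd 4, clipped to [2, 41]) so the quality mask is exercised.
Edits at different positions are independent by default;
`coedit_correlation` ∈ [0, 1) reuses a shared per-read uniform draw with
that probability, which induces positive co-editing while preserving every
marginal exactly.

Each pool carries its truth: configured marginals, realized (empirical)
per-position frequencies with deletion-excluded denominators, realized
outcome-class fractions, and — for independent edits — closed-form
expected class fractions.  "Equals truth exactly" statements refer to the
realized pool, since configured marginals are only attained in
expectation.  The zero-noise regime (`zero_noise`) sets the miscall and
indel rates to zero *and* the quality spread to zero: random sub-30
qualities would mask random bases and change estimates by subsampling,
which is noise rather than pipeline error.

What the simulator does not emulate: adapter read-through (reads are
insert-only; real data should be adapter-trimmed upstream), quality-score
correlation along the read and miscalls conditional on quality, PCR
jackpotting/duplicates, chimeric amplicons, and large structural variants.
Passing tests therefore demonstrate correctness of the analysis chain on
overlap-merged, single-locus data, not robustness to library artefacts.

## Scenario presets and verification sizes

Three seeded presets shape the test conditions: `broad-window-cbe` (A3A-like
CBE with appreciable bystander tails), `focused-inhibitor` (the same editor
with IR 0.1 on-target / 0.9 out-of-window, i.e. a construction selectivity
fold of exactly 9.0), and `abe` (window 4–7).  The verification suite runs
at coverages of 1,000–10,000 reads per sample and 20 seeded runs for the
frequency-recovery grid {0.05, 0.2, 0.5, 0.8}; these sizes put binomial
standard errors well below the tolerances being checked while keeping the
whole suite fast.  The alignment oracle check uses 500 random pairs up to
150 nt; the classifier oracle enumerates all 32,551 alleles with ≤ 3
substitutions of the 20-nt protospacer.

## Known limitations

- Insertion placement follows the aligner's (leftmost-equivalent) gap
  choice; insertion-position bookkeeping is convention-bound in
  homopolymers.
- Identity is measured per read against the single known amplicon; heavily
  truncated reads pass if their aligned fraction is accurate, so very short
  off-target fragments are guarded only by the identity and merge filters.
- The selectivity fold is a ratio of pooled means; with very few defined
  out-of-window positions it is a noisy statistic, and the t test inherits
  the usual small-n caveats.
- No multiple-testing correction across sites is applied (single-locus
  contrasts are reported as-is).
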