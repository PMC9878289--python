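# Methods

## Problem and model

The screen answers one qualitative question per sample: is *SMN1* exon 7
absent on both alleles?  *SMN1* and *SMN2* differ by only a handful of
paralog-specific variants (PSVs), so short reads from either gene co-map to
the *SMN1* reference with mapping quality near zero.  The caller therefore
treats mapping position as paralog-agnostic and uses only the bases reads
carry at configured PSV positions.  Three design commitments follow:

- **MAPQ is never used to filter SMN-region reads.**  Filtering multi-mappers
  would discard essentially all evidence at a segmental duplication.
- **Per-site base counting feeds the copy-number score**; a per-read majority
  vote (tie → AMBIGUOUS, so ambiguous reads never add *SMN1* support) is
  exposed separately for read-level reporting.  Base observations require
  quality ≥ Q20 and exclude N.
- **Ungapped offset arithmetic** extracts PSV bases.  Records whose CIGAR
  contains indels, splices or clips are skipped with a warning rather than
  risking an off-register base.  This is exact for the simulator's reads and
  conservative for real data (a full CIGAR walk is a known limitation).

## Coverage score

Control genes are autosomal and assumed diploid in every sample, so half the
mean control-gene depth d_c estimates the sequencing depth contributed by a
single gene copy.  With n₁ᵢ the *SMN1*-supporting count at PSV site i,

    score = meanᵢ [ n₁ᵢ / (d_c / 2) ]

in copy-equivalents: ~0 under homozygous deletion, ~1 for carriers, ~2
for two-copy samples.  Normalising by control genes (rather than by total
SMN1+SMN2 depth) makes the score robust to *SMN2* copy-number variation;
per-site scores are exposed so alternative normalisations can be layered on.

The deletion cutoff is 0.5 copy-equivalents — the midpoint between the
0-copy and 1-copy clusters, giving maximal margin against both error-driven
false *SMN1* support (which inflates a 0-copy score) and depth noise (which
deflates a 1-copy score).  At the default study conditions the two clusters
are separated by roughly 30 standard deviations, so the exact cutoff value
within (0.1, 0.8) is uncritical; it is configurable.

## Sample QC

A sample FAILs — and is never called — if any of these hold, tested in
order, strictly below threshold (a sample at exactly 20.0X passes):

| rule | default | rationale |
|---|---|---|
| mean control-gene depth < 20X | 20.0 | assay's stated failure rule |
| mean PSV total depth < 20 | 20.0 | a deletion call must rest on present, not missing, data; symmetric with the control rule |
| uniformity < 0.95 | 0.95 | fraction of control bases with depth ≥ 0.2 × mean; the assay's attained uniformity adopted as a floor |

An upstream wet-lab failure ("insufficient pre-capture library") is modelled
only as a boolean flag that forces FAIL.  FAIL samples are excluded from the
sensitivity/specificity 2×2 cells and reported via a separate failure rate;
an undefined ratio (no positives in truth) is reported as not applicable,
never as 0.  Confidence intervals are deliberately not computed: the screen
output is qualitative.

## Simulator

The generator emulates the post-alignment view of a hybridisation-capture
panel and defines the study conditions used throughout the tests:

- **Templates.** Deterministic pseudo-random sequences (seeded from the
  interval coordinates) span each target interval plus a 1 kb flank; the
  *SMN1* and *SMN2* templates are identical except at the PSV positions.
- **Depth.** Each *SMN* gene copy contributes `haploid_depth` (default 50)
  fold-coverage; control intervals are always diploid (2×).  Fragment count
  is Poisson with mean depth·(L + f̄ − 1)/(2·read_length) and fragment starts
  are uniform over the flank-extended window, so expected coverage is exactly
  the target depth at every position of the interval (no edge attenuation).
- **Fragments.** 2×150 bp proper pairs (read 2 reverse, reference-forward
  SEQ); fragment length normal 300 ± 30, truncated at ±3 SD — a typical
  capture-library insert.  Single-end mode exists for completeness.
- **Errors and qualities.** Each base is substituted to a uniformly chosen
  different base with probability `error_rate` (default 10⁻³).  Qualities are
  constant Q30 — errors are *silent*, as miscalled bases at high confidence
  are the dangerous case for a 0-copy score.  Quality filtering is exercised
  through a separate low-quality injection option instead.
- **Coordinates and MAPQ.** All SMN-derived reads (including *SMN2*'s) are
  reported at SMN1-anchored coordinates with MAPQ 0; control reads get
  MAPQ 60.
- **Determinism.** One `numpy` Generator per sample, seeded as
  `base_seed + sample_index`; identical inputs give byte-identical SAM.

Not modelled: capture-efficiency/GC bias, indels, duplicate reads,
gene-conversion and hybrid *SMN1/SMN2* alleles, real flanking sequence
context.  Consequently, passing simulation experiments demonstrates the
*algorithm* (paralog attribution, normalisation, QC, decision rule) under
controlled truth; it does not validate performance on real libraries, where
capture bias and hybrid alleles are the known residual risks (a real
programme confirms positives orthogonally, e.g. by MLPA).

## Locus geometry and cohort composition (desk scale)

The packaged model covers a 1,001 bp SMN capture window (chr5:70247300–
70248300) containing the exon 7 target and all three PSVs, and three 600 bp
control targets labelled after representative panel genes (ACADM, GALT,
PAH) — large enough for stable depth/uniformity statistics, small enough
that a 2,552-sample cohort simulates and calls in a few minutes on one CPU.
The two outer PSV sites' base identities are explicit, editable placeholders
in the config; only chr5:70247773 (c.840 C/T) is the canonical documented
paralog difference.  Validation-panel genotypes: 12 samples with 0 *SMN1*
copies (*SMN2* ∈ {1,2,3}) and 4 with 1–2 copies.  Population cohorts draw
*SMN1* copies from {1,2,3} with weights 0.02/0.93/0.05 (carrier-like
frequency) and *SMN2* from {0..3} with weights 0.05/0.15/0.65/0.15.

## Numerical and edge-case choices

- Coordinates are 1-based inclusive throughout (SAM/VCF convention).
- Zero control depth: uniformity is defined as 0 and the coverage score is
  an error — such samples must fail QC first, and do.
- Read pairs are counted as independent reads in pileup and depth (no
  pair-aware deduplication); mates that both cover a PSV contribute two
  observations, consistently for SMN and control regions so the
  normalisation is unbiased.
- An unreadable SAM in a batch yields a FAIL row ("unreadable input") and
  the batch continues.
- The per-sample JSON report's timestamp is its only non-deterministic
  field and lives in a dedicated key so reruns can be diffed.

## Limitations

- SMN2 copy number, carrier detection, and SNVs in *SMN1* are out of scope
  by design; the screen's only positive finding is the homozygous exon 7
  deletion.
- Calls are machine output; a screening programme adds human review and
  orthogonal confirmation downstream.
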