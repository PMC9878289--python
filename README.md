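# smnscreen

Newborn screening for spinal muscular atrophy (SMA) from targeted NGS data.

SMA is caused, in >95% of cases, by the homozygous deletion of *SMN1* exon 7.
Detecting it from short reads is hard because *SMN1* and its paralog *SMN2*
are nearly identical: an aligner co-maps reads from both genes onto *SMN1*
with mapping quality ~0, so neither position nor MAPQ can tell the paralogs
apart. `smnscreen` implements the screening algorithm of a capture-panel
NGS assay for this problem, plus an aligned-read simulator so the assay's
validation experiments can be reproduced entirely on a desktop.

**Who it is for:** bioinformaticians building or evaluating NGS-based
newborn-screening pipelines, and anyone who wants a compact, tested reference
implementation of PSV-based paralog copy-number calling.

## The method

1. **Paralog-specific variants (PSVs).** Three genomic positions inside the
   *SMN1* exon 7 target region (hg38 chr5:70247724, 70247773, 70247921) carry
   different bases in *SMN1* and *SMN2*. Each read covering a PSV contributes
   one base observation (base quality ≥ Q20, N excluded); per-site pileup
   counts n₁ (matching the *SMN1* base), n₂ (*SMN2* base) and other are
   accumulated. Reads are never filtered on MAPQ — at a segmental duplication
   every informative read is a multi-mapper.
2. **Coverage score.** Control genes are diploid, so half the mean
   control-gene depth d_c is the depth one gene copy contributes. The score

       score = mean over PSV sites i of  n₁ᵢ / (d_c / 2)

   is the estimated *SMN1* exon 7 copy number: ~0 for a homozygous deletion,
   ~1 for a carrier, ~2 for unaffected.
3. **QC.** A sample fails if mean control-gene depth < 20X, if mean PSV depth
   < 20, or if coverage uniformity (fraction of control bases with depth
   ≥ 0.2 × mean) < 0.95. Failed samples are never called.
4. **Call.** A QC-passing sample with score < 0.5 copy-equivalents is screen
   **POSITIVE** (homozygous deletion); everything else — including carriers —
   is **NEGATIVE**. Batch evaluation against truth uses
   sensitivity = TP/(TP+FN) and specificity = TN/(TN+FP).

The simulator emits already-aligned 2×150 bp read pairs (SAM) from *SMN1*/
*SMN2* templates that differ only at the PSVs, Poisson depth per gene copy,
uniform substitution errors, and a truth table — the exact input boundary of
the caller.

## Worked example

```bash
python examples/01_screen_single_sample.py
```

```
simulated 2776 aligned reads for genotype SMN1=1, SMN2=1
mean control-gene depth :  101.7x
coverage uniformity     :  1.000
PSV total depth         :  109.7
coverage score          :  0.865 copy-equivalents
per-site scores         : 0.787, 0.846, 0.964
screen call             : NEGATIVE
```

A carrier simulated at 50x haploid depth scores ~0.9 copy-equivalents —
well above the 0.5 cutoff, so the screen is NEGATIVE: the assay detects only
the homozygous deletion. `examples/02_blinded_validation_panel.py` runs the
12-positive / 4-negative validation panel (TP=12, FN=0, FP=0, TN=4 →
sensitivity and specificity 100%), and `examples/03_population_screen.py`
a scaled-down population run.

The same workflow is available from the shell:

```bash
smn-screen simulate --genotypes genotypes.tsv --depth 50 --seed 1 --out sim/
smn-screen batch --manifest sim/manifest.tsv --truth sim/truth.tsv --out out/
```

`batch` writes a per-sample TSV, one JSON report per sample, a score scatter
with the cutoff line, and a confusion summary when truth is given.

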