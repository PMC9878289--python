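# Default locus model for SMN1 exon 7 deletion screening (hg38 coordinates).
#
# PSV sites are the paralog-specific variant positions used to attribute a
# read to SMN1 or SMN2.  SMN2-derived reads are assumed co-mapped to SMN1
# coordinates, so one coordinate addresses both paralogs.  The base pair at
# chr5:70247773 is the canonical exon 7 c.840 C (SMN1) / T (SMN2) paralog
# difference.  The base pairs at the two flanking sites are PLACEHOLDERS:
# edit them to the discriminating bases of your assay before use on real data.
psv_sites:
  - {chrom: chr5, pos: 70247724, smn1_base: G, smn2_base: A}  # placeholder bases
  - {chrom: chr5, pos: 70247773, smn1_base: C, smn2_base: T}  # c.840C>T
  - {chrom: chr5, pos: 70247921, smn1_base: A, smn2_base: G}  # placeholder bases

# Target interval containing all PSV positions (exon 7 plus flank).
exon7: {chrom: chr5, start: 70247700, end: 70247940, label: SMN1 exon 7 target}

# Capture region enclosing exon7; simulated reads are drawn over this span.
smn_region: {chrom: chr5, start: 70247300, end: 70248300, label: SMN1 exon 7 capture region}

# Diploid control-gene target intervals used for depth normalisation and QC.
# Representative exonic targets of three unrelated panel genes.
control_genes:
  - {chrom: chr1, start: 75724401, end: 75725000, label: ACADM}
  - {chrom: chr9, start: 34646001, end: 34646600, label: GALT}
  - {chrom: chr12, start: 102840001, end: 102840600, label: PAH}

thresholds:
  min_control_depth: 20.0      # mean control-gene coverage; fail if strictly below
  min_uniformity: 0.95         # fraction of control bases with depth >= 0.2 x mean
  min_base_quality: 20         # Phred floor for PSV base evidence
  deletion_score_cutoff: 0.5   # coverage score below this => screen positive
  min_psv_total_depth: 20.0    # mean total depth across PSV sites
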