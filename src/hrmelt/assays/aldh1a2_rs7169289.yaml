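# ALDH1A2 rs7169289 (A>G) HRM assay.
# The MINOR allele (G) carries the G.C pair here, so the minor homozygote
# melts at the higher temperature.
assay_id: ALDH1A2
rs_id: rs7169289
major_allele: A
minor_allele: G
gc_allele: G
tm_gc_hom_c: 85.0
delta_tm_hom_c: 0.72
het_penalty_c: 1.0
het_split_c: 0.0
width_hom_c: 0.35
width_het_c: 0.525
amplicon_length_bp: 124
snp_position_bp: 57
vcf:
  chrom: UNPLACED   # placeholder: genomic coordinates are not part of the assay
  pos: 1
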