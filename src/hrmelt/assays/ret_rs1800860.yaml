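# RET rs1800860 (G>A) HRM assay.
# Amplicon geometry and homozygote Tm separation from the published assay;
# absolute Tm, widths and heteroduplex penalty are melt-model defaults.
assay_id: RET
rs_id: rs1800860
major_allele: G
minor_allele: A
gc_allele: G
tm_gc_hom_c: 85.0
delta_tm_hom_c: 0.50
het_penalty_c: 1.0
het_split_c: 0.0
width_hom_c: 0.35
width_het_c: 0.525
amplicon_length_bp: 95
snp_position_bp: 33
vcf:
  chrom: UNPLACED   # placeholder: genomic coordinates are not part of the assay
  pos: 1
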