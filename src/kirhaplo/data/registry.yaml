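# Canonical KIR locus and gene-content motif registry.
#
# Loci are counted conservatively: 11 genes and 2 pseudogenes.  Allele-level
# names that behave as alleles of a single locus (2DL2/2DL3, 3DL1/3DS1,
# 2DS3/2DS5, positional 2DL5A/2DL5B) are recorded as aliases of the shared
# locus.  Motif gene orders are written at allele/alias level because motif
# identity depends on which allele-lineage is carried (cA01 carries 2DL3,
# cB01/cB02 carry 2DL2).
loci:
  - locus_id: 3DL3
    kind: gene
    framework: true
  - locus_id: 2DS2
    kind: gene
  - locus_id: 2DL2L3
    kind: gene
    allele_aliases: [2DL2, 2DL3]
  - locus_id: 2DL5
    kind: gene
    allele_aliases: [2DL5A, 2DL5B]
  - locus_id: 2DS3S5
    kind: gene
    allele_aliases: [2DS3, 2DS5]
  - locus_id: 2DP1
    kind: pseudogene
  - locus_id: 2DL1
    kind: gene
  - locus_id: 3DP1
    kind: pseudogene
    framework: true
  - locus_id: 2DL4
    kind: gene
    framework: true
  - locus_id: 3DL1S1
    kind: gene
    allele_aliases: [3DL1, 3DS1]
  - locus_id: 2DS1
    kind: gene
  - locus_id: 2DS4
    kind: gene
  - locus_id: 3DL2
    kind: gene
    framework: true

motifs:
  - motif_id: cA01
    side: Cen
    gene_order: [3DL3, 2DL3, 2DP1, 2DL1]
  - motif_id: cB01
    side: Cen
    gene_order: [3DL3, 2DS2, 2DL2, 2DL5B, 2DS3S5, 2DP1, 2DL1]
  - motif_id: cB02
    side: Cen
    gene_order: [3DL3, 2DS2, 2DL2]
  - motif_id: cB03
    side: Cen
    gene_order: [3DL3, 2DS2, 2DL3, 2DP1, 2DL1]
  - motif_id: tA01
    side: Tel
    gene_order: [2DL4, 3DL1, 2DS4, 3DL2]
  - motif_id: tB01
    side: Tel
    gene_order: [2DL4, 3DS1, 2DL5A, 2DS3S5, 2DS1, 3DL2]

# The seven gene-content haplotypes observed in the 192-donor reference panel;
# cB03|tB01 is the one combination of the four Cen and two Tel motifs that has
# not been observed.
haplotypes:
  - cA01|tA01
  - cA01|tB01
  - cB01|tA01
  - cB01|tB01
  - cB02|tA01
  - cB02|tB01
  - cB03|tA01
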