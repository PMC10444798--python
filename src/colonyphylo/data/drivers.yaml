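# Driver-gene screen configuration.
# Classes: sds_associated = genes recurrently mutated / under selection in
# Shwachman-Diamond haematopoiesis; ch_cancer = known clonal-haematopoiesis
# and haematological-malignancy genes. Dosage regions flag LOH/CNA intervals
# whose loss alters the germline ribosomopathy lesion dosage (GRCh37
# coordinates). Edit freely: the screen is annotation-based.
sds_associated:
  - TP53
  - EIF6
  - RPL5
  - RPL22
  - PRPF8
ch_cancer:
  - ASXL1
  - BCOR
  - CALR
  - CBL
  - CSF3R
  - CUX1
  - DNMT3A
  - EZH2
  - GATA2
  - GNAS
  - GNB1
  - IDH1
  - IDH2
  - JAK2
  - KIT
  - KRAS
  - MLL3
  - MPL
  - NF1
  - NFE2
  - NRAS
  - PHF6
  - PPM1D
  - PTPN11
  - RB1
  - RUNX1
  - SETBP1
  - SF3B1
  - SRSF2
  - SH2B3
  - STAG2
  - TET2
  - TP53
  - U2AF1
  - ZRSR2
nonsynonymous_tokens:
  - missense
  - nonsense
  - stop_gained
  - stop_lost
  - start_lost
  - frameshift
  - splice
  - inframe
dosage_regions:
  - gene: SBDS
    chrom: "7"
    start: 66452690
    end: 66460588
  - gene: EFL1
    chrom: "15"
    start: 82422000
    end: 82552000
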