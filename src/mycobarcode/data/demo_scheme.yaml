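# Demonstration primer scheme (fixture data).
#
# Locus primers are the standard fITS7 (forward) / ITS4 (reverse) pair
# targeting nrITS2, and the CS tags are the public Fluidigm consensus
# sequences CS1/CS2.  The eight 5-bp inline barcodes below are a SYNTHETIC
# demonstration set (pairwise Hamming distance >= 3, as the loader requires);
# they are NOT the barcode set used in any published study.  Heterogeneity
# spacers cover lengths 0-6 (forward) and 0-4 (reverse).
forward_primer: GTGARTCATCGAATCTTTG     # fITS7
reverse_primer: TCCTCCGCTTATTGATATGC    # ITS4
cs1_tag: ACACTGACGACATGGTTCTACA         # Fluidigm CS1
cs2_tag: TACGGTAGCAGAGACTTGGTCT         # Fluidigm CS2
forward_spacers:
  - ""
  - "T"
  - "CA"
  - "GTC"
  - "AGCT"
  - "TCAGC"
  - "GATCGA"
reverse_spacers:
  - ""
  - "G"
  - "TC"
  - "ATG"
  - "CGAT"
barcodes:
  - ATGCC
  - TTCAC
  - CCACG
  - GATCG
  - CTTCA
  - TCTAG
  - TCAGA
  - CGCTT
min_trimmed_length: 200
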