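{
  "markers": [
    {"marker_id": "Cerast_31", "locus_id": "Cerast_31", "tag_id": "Cerast_31", "allele_A": "A", "allele_B": "G", "placement": {"chrom": "MN178488", "start": 140}},
    {"marker_id": "Cerast_450", "locus_id": "Cerast_450", "tag_id": "Cerast_450", "allele_A": "A", "allele_B": "T", "placement": {"chrom": "MN178489", "start": 164}},
    {"marker_id": "Cerast_456", "locus_id": "Cerast_456", "tag_id": "Cerast_456", "allele_A": "C", "allele_B": "T", "placement": {"chrom": "MN178490", "start": 89}},
    {"marker_id": "Cerast_586", "locus_id": "Cerast_586", "tag_id": "Cerast_586", "allele_A": "C", "allele_B": "T", "placement": {"chrom": "MN178491", "start": 153}},
    {"marker_id": "Cerast_1173A", "locus_id": "Cerast_1173A", "tag_id": "Cerast_1173A", "allele_A": "A", "allele_B": "G", "placement": {"chrom": "MN178492", "start": 128}},
    {"marker_id": "Cerast_1255", "locus_id": "Cerast_1255", "tag_id": "Cerast_1255", "allele_A": "A", "allele_B": "T", "placement": {"chrom": "MN178493", "start": 114}},
    {"marker_id": "Cerast_1316", "locus_id": "Cerast_1316", "tag_id": "Cerast_1316", "allele_A": "T", "allele_B": "C", "placement": {"chrom": "MN178494", "start": 54}},
    {"marker_id": "Cerast_1400", "locus_id": "Cerast_1400", "tag_id": "Cerast_1400", "allele_A": "G", "allele_B": "A", "placement": {"chrom": "MN178495", "start": 98}},
    {"marker_id": "Cerast_2530", "locus_id": "Cerast_2530", "tag_id": "Cerast_2530", "allele_A": "T", "allele_B": "A", "placement": {"chrom": "MN178496", "start": 125}}
  ],
  "provenance": []
}
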