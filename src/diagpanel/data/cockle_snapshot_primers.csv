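marker_id,tailed_sequence,sense
Cerast_1173A,gactTGGTGGGCACTTGGATGC,R
Cerast_1316,gactgactgacGCAACAGATTGCCAGCTGT,R
Cerast_1400,gactgactgactACTCTTCTTCATGGTTGAAAAGTC,F
Cerast_456,gactgactgactgactgactgaCAGAAGGATGCGGCATTGT,F
Cerast_31,gactgactgactgactgactgacATGATTAAGCAAGCTACTGCTAG,F
Cerast_1255,gactgactgactgactgactgactgactgaATTGATTCGCAGTGTTTTGCT,R
Cerast_586,gactgactgactgactgactgactgactgactgactgacATGGGCATGCGCAAAGG,F
Cerast_450,gactgactgactgactgactgactgactgactgactgactCATTATAAATTCCTAGCGAGCAGA,F
Cerast_2530,gactgactgactgactgactgactgactgactgactgactgactgactTGAATTTTGGCATGTTTTTGCTCTAG,R
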