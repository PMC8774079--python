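line_id	parent_genotype	genotype	count
AhSLF1#1	S3,S3L	S3S3	5
AhSLF1#1	S3,S3L	S3S3L	11
AhSLF1#1	S3,S3L	S3LS3L	6
AhSLF2#1	S3,S3L	S3S3	6
AhSLF2#1	S3,S3L	S3S3L	10
AhSLF2#1	S3,S3L	S3LS3L	5
AhSLF3#1	S3,S3L	S3S3	4
AhSLF3#1	S3,S3L	S3S3L	12
AhSLF3#1	S3,S3L	S3LS3L	6
AmChr7-SLFL1#1	S3,S3L	S3S3L	10
AmChr7-SLFL1#1	S3,S3L	S3LS3L	12
AmChr7-SLFL1#1	S3,S3L	S3S3	0
PaS4-SLFL1#1	S3,S3L	S3S3	6
PaS4-SLFL1#1	S3,S3L	S3S3L	12
PaS4-SLFL1#1	S3,S3L	S3LS3L	4
PaS4-SLFL2#1	S3,S3L	S3S3	5
PaS4-SLFL2#1	S3,S3L	S3S3L	9
PaS4-SLFL2#1	S3,S3L	S3LS3L	7
PaSFB1#1	S3,S3L	S3S3	7
PaSFB1#1	S3,S3L	S3S3L	10
PaSFB1#1	S3,S3L	S3LS3L	5
PaSFB4#1	S3,S3L	S3S3	5
PaSFB4#1	S3,S3L	S3S3L	13
PaSFB4#1	S3,S3L	S3LS3L	5
MdSFBBb-S9#1	S3,S3L	S3S3	6
MdSFBBb-S9#1	S3,S3L	S3S3L	11
MdSFBBb-S9#1	S3,S3L	S3LS3L	6
AcSc4SLF4#1	S3,S3L	S3S3	12
AcSc4SLF4#1	S3,S3L	S3S3L	10
AcSc4SLF4#1	S3,S3L	S3LS3L	0
AcSc4SLF5#1	S3,S3L	S3S3	5
AcSc4SLF5#1	S3,S3L	S3S3L	12
AcSc4SLF5#1	S3,S3L	S3LS3L	6
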