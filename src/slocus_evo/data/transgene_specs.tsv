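transgene_id	source_species	targets
ShS5-SLF5	Solanum habrochaites	S3L
ShS5-SLF6	Solanum habrochaites	S3
AhSLF1	Antirrhinum hispanicum	S3,S3L
AhSLF2	Antirrhinum hispanicum	S3,S3L
AhSLF3	Antirrhinum hispanicum	S3,S3L
AmChr7-SLFL1	Antirrhinum majus	S3L
PaS4-SLFL1	Prunus avium	S3,S3L
PaS4-SLFL2	Prunus avium	S3,S3L
PaSFB1	Prunus avium	S3,S3L
PaSFB4	Prunus avium	S3,S3L
MdSFBBb-S9	Malus domestica	S3,S3L
AcSc4SLF4	Aquilegia coerulea	S3
AcSc4SLF5	Aquilegia coerulea	S3,S3L
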