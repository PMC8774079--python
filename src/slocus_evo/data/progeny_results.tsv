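line_id	parent_genotype	genotype	count
ShS5-SLF5#2	S3,S3L	S3S3L	12
ShS5-SLF5#2	S3,S3L	S3LS3L	9
ShS5-SLF5#2	S3,S3L	S3S3	0
ShS5-SLF5#5	S3,S3L	S3S3L	14
ShS5-SLF5#5	S3,S3L	S3LS3L	9
ShS5-SLF5#5	S3,S3L	S3S3	0
ShS5-SLF6#1	S3,S3L	S3S3	11
ShS5-SLF6#1	S3,S3L	S3S3L	12
ShS5-SLF6#1	S3,S3L	S3LS3L	0
ShS5-SLF6#3	S3,S3L	S3S3	13
ShS5-SLF6#3	S3,S3L	S3S3L	10
ShS5-SLF6#3	S3,S3L	S3LS3L	0
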