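# Packaged per-amino-acid backbone chemical-shift statistics (synthetic,
# BMRB-like reference table authored for this package): mean and standard
# deviation in ppm for each backbone resonance of each standard residue type.
# Proline has no amide H/N; glycine has no CB.
aa	resonance	mean	sd
A	H	8.20	0.60
A	N	123.2	3.6
A	CA	53.1	2.0
A	CB	19.0	1.8
A	CO	177.7	2.1
R	H	8.24	0.61
R	N	120.8	3.7
R	CA	56.8	2.3
R	CB	30.7	1.8
R	CO	176.4	2.0
N	H	8.35	0.63
N	N	118.9	4.0
N	CA	53.5	1.9
N	CB	38.7	1.7
N	CO	175.2	1.8
D	H	8.31	0.58
D	N	120.6	3.9
D	CA	54.7	2.0
D	CB	40.9	1.6
D	CO	176.4	1.8
C	H	8.38	0.67
C	N	120.1	4.5
C	CA	58.2	3.3
C	CB	32.8	6.1
C	CO	174.8	2.0
Q	H	8.22	0.59
Q	N	119.9	3.6
Q	CA	56.6	2.1
Q	CB	29.2	1.8
Q	CO	176.3	1.9
E	H	8.33	0.60
E	N	120.7	3.5
E	CA	57.4	2.1
E	CB	30.0	1.7
E	CO	176.9	1.9
G	H	8.33	0.64
G	N	109.7	3.8
G	CA	45.4	1.3
G	CO	174.0	1.8
H	H	8.25	0.68
H	N	119.6	4.0
H	CA	56.5	2.3
H	CB	30.2	2.1
H	CO	175.3	2.0
I	H	8.26	0.69
I	N	121.5	4.3
I	CA	61.6	2.7
I	CB	38.6	2.0
I	CO	175.9	1.9
L	H	8.22	0.65
L	N	121.9	3.9
L	CA	55.7	2.1
L	CB	42.3	1.9
L	CO	177.0	2.0
K	H	8.22	0.60
K	N	121.1	3.8
K	CA	56.9	2.2
K	CB	32.8	1.8
K	CO	176.7	1.9
M	H	8.26	0.60
M	N	120.1	3.5
M	CA	56.1	2.2
M	CB	32.9	2.2
M	CO	176.3	2.1
F	H	8.36	0.72
F	N	120.4	4.2
F	CA	58.1	2.6
F	CB	39.9	2.1
F	CO	175.5	2.0
P	CA	63.3	1.5
P	CB	31.8	1.2
P	CO	176.7	1.5
S	H	8.28	0.59
S	N	116.3	3.5
S	CA	58.7	2.1
S	CB	63.8	1.5
S	CO	174.6	1.8
T	H	8.25	0.61
T	N	115.4	4.7
T	CA	62.2	2.6
T	CB	69.7	1.6
T	CO	174.5	1.8
W	H	8.29	0.78
W	N	121.7	4.1
W	CA	57.7	2.6
W	CB	29.9	2.0
W	CO	176.1	2.0
Y	H	8.32	0.73
Y	N	120.5	4.2
Y	CA	58.1	2.5
Y	CB	39.2	2.2
Y	CO	175.4	2.0
V	H	8.27	0.67
V	N	121.1	4.6
V	CA	62.5	2.9
V	CB	32.6	1.8
V	CO	175.7	1.9
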