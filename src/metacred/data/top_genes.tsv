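gene	chromosome	n_minor	quality	or_caucasian	or_asian	or_all	or_all_alt
APOE	19	4167	AAA	3.77 (3.29-4.32)	3.99 (2.86-5.57)	3.61 (3.20-4.08)
CLU	8	53712	AAA	0.87 (0.85-0.90)	n.a	0.88 (0.86-0.91)
PICALM	11	44358	AAA	0.89 (0.86-0.92)	n.a	0.90 (0.86-0.93)
EXOC3L2	19	13519	AAA	1.17 (1.12-1.23)	n.a	1.17 (1.12-1.23)
BIN1	2	24713	AAA	1.14 (1.08-1.21)	n.a	1.14 (1.08-1.21)
CR1	1	18779	AAA	1.14 (1.08-1.20)	n.a	1.16 (1.09-1.22)
SORL1	11	1734	AAA	1.07 (1.00-1.15)	1.30 (1.13-1.50)	1.10 (1.02-1.17)
TNK1	17	3538	AAA	0.84 (0.76-0.93)	n.a	0.84 (0.76-0.93)
IL8	4	1157	AAA	1.26 (1.01-1.58)	n.a	1.26 (1.01-1.58)
LDLR	19	1228	AAA	0.85 (0.72-0.89)	n.a	0.85 (0.72-0.89)	0.85 (0.72-0.99)
CST3	20	1203	AAA	1.28 (1.04-1.56)	n.a	1.23 (1.03-1.48)
CHRNB2	1	227	BAA	0.69 (0.51-0.95)	n.a	0.67 (0.50-0.90)
SORCS1	10	567	BAA	1.34 (1.09-1.65)	n.a	1.34 (1.09-1.65)
TNF	6	301	BAA	n.a	1.37 (1.05-1.79)	1.35 (1.39-1.77)
CCR2	3	308	BAA	0.73 (0.56-0.97)	n.a	0.73 (0.56-0.97)
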