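parameter	dG_bulk	dG_cat_122	dG_ev	dG_wa	m_peg	m_diol
AA/UU	-0.70	-0.00	-0.22	0.35	7.1	2.9
AU/UA	-0.22	-0.30	-0.22	0.19	3.9	1.6
UA/AU	-1.22	-0.08	-0.22	0.19	3.9	1.6
CA/GU	-1.69	-0.09	-0.22	-0.14	-2.9	-1.2
GU/CA	-1.73	-0.41	-0.22	0.56	11.4	4.7
CU/GA	-1.52	-0.28	-0.22	0.25	5.1	2.1
GA/CU	-2.06	-0.16	-0.22	0.20	4.1	1.7
CG/GC	-2.00	-0.18	-0.22	0.24	4.9	2.0
GC/CG	-2.72	-0.58	-0.22	0.45	9.2	3.8
GG/CC	-2.92	-0.18	-0.22	0.43	8.8	3.6
initiation	4.09	0.0	-0.22	1.63	33.3	13.7
terminal_AU	0.45	0.0	NA	0.40	8.2	3.4
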