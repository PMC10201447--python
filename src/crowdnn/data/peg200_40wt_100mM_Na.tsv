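parameter	dH_kcal	dH_err_kcal	dS_cal	dS_err_cal	dG37_kcal	dG37_err_kcal
AA/UU	-10.0	0.1	-30.4	0.2	-0.57	0.05
AU/UA	-10.1	0.1	-30.8	0.1	-0.55	0.03
UA/AU	-11.1	0.4	-31.5	0.8	-1.33	0.09
CA/GU	-12.1	0.3	-32.1	0.6	-2.14	0.08
GU/CA	-10.7	0.2	-28.7	0.1	-1.80	0.16
CU/GA	-11.2	0.3	-30.4	0.3	-1.77	0.17
GA/CU	-11.7	0.2	-30.5	0.3	-2.24	0.07
CG/GC	-11.1	0.5	-28.8	1.1	-2.16	0.16
GC/CG	-13.8	0.1	-34.6	0.1	-3.07	0.01
GG/CC	-14.8	0.1	-38.4	0.1	-2.89	0.06
initiation	4.6	2.0	-2.9	6.1	5.50	0.11
terminal_AU	6.5	0.1	18.2	0.1	0.85	0.92
symmetry	0	0	-1.4	0	0.43	0
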