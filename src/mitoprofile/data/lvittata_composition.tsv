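# Published composition and skewness of the Lysmata vittata mitogenome
# (GenBank MT478132): whole genome and pooled PCG rows, then per-gene,
# pooled tRNA/rRNA and control-region rows.  Percentages of T, C, A, G,
# the A+T content, and the printed AT/GC skews.
region	size_bp	pct_T	pct_C	pct_A	pct_G	at_content	at_skew	gc_skew
whole genome	22003	37.15	16.69	34.35	11.80	71.50	-0.039	-0.172
PCGs	11144	41.09	15.25	28.70	14.96	69.79	-0.178	-0.010
atp6	675	40.15	19.41	28.30	12.15	68.44	-0.17	-0.23
atp8	165	43.64	15.76	35.15	5.45	78.79	-0.11	-0.49
cob	1137	39.40	20.14	27.88	12.58	67.28	-0.17	-0.23
cox1	1614	37.73	17.91	27.76	16.60	65.49	-0.15	-0.04
cox2	693	37.95	19.77	28.43	13.85	66.38	-0.14	-0.18
cox3	756	39.29	18.25	27.91	14.55	67.20	-0.17	-0.11
nad1	927	44.01	10.79	27.29	17.91	71.31	-0.23	0.25
nad2	1005	43.28	18.01	29.05	9.65	72.34	-0.20	-0.30
nad3	354	42.66	18.93	26.27	12.15	68.93	-0.24	-0.22
nad4	1336	43.11	9.51	28.59	18.79	71.70	-0.20	0.33
nad4l	246	45.12	7.72	26.02	21.14	71.14	-0.27	0.46
nad5	1732	41.17	9.82	31.64	17.38	72.81	-0.13	0.26
nad6	504	44.64	17.06	28.57	9.72	73.21	-0.22	-0.27
tRNAs	1512	33.27	14.02	36.31	16.40	69.58	0.04	0.08
rRNAs	2315	32.40	11.88	36.89	18.83	69.29	0.06	0.23
CR1	650	42.15	9.85	38.31	9.69	80.46	-0.05	-0.01
CR2	3821	38.50	14.39	33.73	13.37	72.23	-0.07	-0.04
CR3	888	42.34	13.51	34.91	9.23	77.25	-0.10	-0.19
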