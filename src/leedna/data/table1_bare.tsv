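# units: 1e-15 cm2
# source: bare plasmid DNA (3197 bp), 1-20 eV
# f: 0.25 0.02
energy_eV	CL	DSB	SSB	LS	BD_CL	NDCD	ISOLATED_BD	TOTAL_BD	TOTAL_DAMAGE
1	1.7 0.5	n.d.	31.6 4.1	37.1 6.1	1.5 1.0	n.d.	37.1 9.6	39.6 12.4	76.7 13.5
2	n.d.	n.d.	30.2 3.1	34.7 3.0	n.d.	n.d.	46.4 9.2	45.5 7.7	80.2 9.4
3	1.0 0.2	n.d.	23.9 4.0	28.8 3.9	0.5 0.3	n.d.	18.7 8.0	21.1 6.9	49.9 7.8
4	1.4 0.3	1.2 0.3	29.8 3.1	36.2 3.9	0.7 0.6	0.7 0.5	21.1 5.7	25.5 5.1	61.6 6.8
5	2.1 0.3	1.5 0.3	37.5 4.7	44.7 5.8	1.1 0.6	1.3 0.8	22.9 9.8	29.9 13.3	74.6 14.3
6	1.5 0.2	2.3 0.2	18.2 2.2	23.8 3.2	0.9 0.5	1.6 1.0	12.2 3.9	12.7 5.4	36.9 5.5
7	1.5 0.1	1.4 0.5	29.5 3.4	37.6 4.7	0.6 0.4	1.1 0.7	23.4 12.5	25.9 12.5	65.5 13.3
8	1.9 0.3	1.6 0.2	36.6 4.2	42.8 4.7	0.8 0.5	1.2 0.9	24.2 4.2	27.9 10.9	70.7 12.1
9	2.0 0.4	2.7 0.6	39.3 4.2	47.3 6.1	1.5 1.0	1.9 1.2	28.2 11.0	37.4 15.3	84.7 16.5
10	3.7 0.8	3.5 0.6	45.5 4.1	52.0 6.4	2.9 1.1	5.1 1.4	54.0 16.4	51.5 19.7	103.5 21.0
11	2.3 0.4	2.6 0.5	35.1 4.5	40.8 5.1	1.1 0.8	1.3 0.8	25.6 13.3	26.5 11.1	67.3 12.1
12	2.1 0.4	2.1 0.4	28.4 2.6	35.3 3.2	0.9 0.4	1.2 0.7	22.8 8.9	23.9 5.0	59.2 6.6
13	1.7 0.2	1.4 0.5	27.7 4.3	33.3 4.7	1.2 0.4	1.2 0.7	19.1 7.9	20.4 6.5	54.6 7.7
14	1.1 0.2	1.3 0.1	27.4 6.9	29.9 4.0	0.8 0.1	0.8 0.6	12.3 7.2	12.6 2.9	42.5 4.3
15	1.2 0.2	1.4 0.4	36.4 3.2	41.2 3.7	1.0 0.2	0.7 0.5	11.0 5.4	12.5 5.1	53.7 6.6
16	1.6 0.2	1.5 0.3	38.2 3.9	43.3 7.8	1.1 0.4	0.9 0.6	9.9 6.4	11.0 3.3	54.3 5.4
17	1.3 0.2	1.4 0.4	40.2 3.8	43.3 5.2	1.5 0.3	1.2 0.5	15.6 5.8	18.3 6.1	61.6 7.7
18	1.7 0.3	1.3 0.3	40.6 7.7	43.8 5.1	1.4 0.5	0.9 0.7	19.0 8.9	20.5 8.1	55.3 9.1
20	1.6 0.3	1.6 0.4	40.8 3.8	44.7 4.5	1.6 0.6	1.1 0.6	23.9 5.3	24.7 5.7	69.4 7.7
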