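# units: 1e-15 cm2
# source: arginine-DNA complex (same 3197 bp plasmids), 5 and 10 eV
# f: 0.25 0.02
energy_eV	CL	DSB	SSB	LS	BD_CL	NDCD	ISOLATED_BD	TOTAL_BD	TOTAL_DAMAGE
5	3.9 0.6	1.4 0.2	8.4 0.7	17.3 0.3	0.8 0.1	0.6 0.3	23.0 0.3	26.5 1.1	45.8 0.7
10	5.7 0.6	2.7 0.8	12.3 1.2	20.0 1.0	4.3 1.9	3.4 2.0	28.2 2.9	35.1 2.3	57.5 2.8
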