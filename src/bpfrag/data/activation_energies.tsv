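bp_id	atoms	carbon_groups	hetero_groups	e_direct	e_rearranged
1	C-N	-C(-NH2)(=O)	none	203	NA
2	C-N	-CH3,=O	-CH3	124	95
3	C-N	-CH3,=O	=CH2	100	68
4	C-N	-C(-OH)(=O),-CH3	none	236	NA
5	C-N	-C(-OH)(=O),-CH3	-C(-CH3)(=O)	197	161
6	C-O	-CH3,=O	none	25	NA
7	C-C	-NH2	=O	-99	NA
8	C-C	-CH3,-NH(-CH3)	=O	-153	NA
9	C-N	-CH3	none	245	NA
10	C-N	-CH3	-C(-NH2)(=NH)	238	132
11	C-N	-CH3	=C(=NH)	206	NA
12	C-N	=NH	-CH3	403	NA
13	C-N	-NH2,=NH	-CH3	105	79
14	C-N	-NH(-CH3),=NH	none	51	NA
15	C-O	-CH3	-C(-CH3)(=O)	NA	105
16	C-O	-CH3,=O	-CH3	28	91
17	C-C	-CH3,-NH2	=O	-129	NA
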