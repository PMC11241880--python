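network	centralization_degree	cluster_count	connectance	edge_count	giant_component_size	hub_count	ks_stat	mean_degree	modularity	node_count
V1-Bst-79X	0.16	7	0.12	627	31	29	0.21	12.29	0.64	102
V6-Bst-79X	0.20	6	0.11	489	36	21	0.24	10.19	0.72	96
R2-Bst-79X	0.11	8	0.06	447	27	19	0.13	7.58	0.81	118
R6-Bst-79X	0.16	6	0.12	719	32	31	0.17	13.31	0.67	108
V1-Ctrl-79X	0.13	5	0.17	700	30	27	0.17	15.56	0.61	90
V6-Ctrl-79X	0.14	5	0.13	485	24	21	0.18	11.02	0.73	88
R2-Ctrl-79X	0.10	5	0.10	399	38	19	0.19	8.77	0.77	91
R6-Ctrl-79X	0.29	5	0.14	951	61	49	0.20	16.12	0.35	118
V1-Bst-10X	0.14	5	0.15	725	29	29	0.20	14.50	0.64	100
V6-Bst-10X	0.14	5	0.17	1398	43	40	0.14	21.51	0.61	130
R2-Bst-10X	0.26	4	0.18	1599	88	61	0.25	24.05	0.25	133
R6-Bst-10X	0.18	6	0.15	1604	49	48	0.18	22.12	0.57	145
V1-Ctrl-10X	0.11	5	0.12	684	29	25	0.18	12.91	0.74	106
V6-Ctrl-10X	0.15	7	0.18	448	56	23	0.18	12.62	0.62	71
R2-Ctrl-10X	0.16	5	0.11	743	56	31	0.18	12.49	0.73	119
R6-Ctrl-10X	0.16	4	0.11	646	53	30	0.17	12.07	0.68	107
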