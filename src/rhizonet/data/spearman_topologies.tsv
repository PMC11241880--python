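network	centralization_degree	cluster_count	connectance	edge_count	giant_component_size	hub_count	ks_stat	mean_degree	modularity	node_count
V1-Bst-79X	0.11	4	0.23	27	6	6	0.44	3.38	0.62	16
V6-Bst-79X	0.06	4	0.22	37	6	6	0.23	3.89	0.71	19
R2-Bst-79X	0.05	7	0.13	55	6	12	0.28	3.67	0.80	30
R6-Bst-79X	0.04	7	0.10	24	4	4	0.36	2.18	0.84	22
V1-Ctrl-79X	0.00	2	0.40	6	3	6	NA	2.00	0.50	6
V6-Ctrl-79X	0.00	2	0.40	6	3	6	NA	2.00	0.50	6
R2-Ctrl-79X	0.06	6	0.13	31	5	5	0.36	2.82	0.79	22
R6-Ctrl-79X	0.13	6	0.16	36	7	7	0.36	3.27	0.63	22
V1-Bst-10X	0.00	2	0.40	6	3	6	NA	2.00	0.50	6
V6-Bst-10X	0.05	6	0.13	34	5	5	0.25	2.96	0.80	23
R2-Bst-10X	0.01	4	0.20	21	4	4	0.36	2.80	0.73	15
R6-Bst-10X	0.08	6	0.14	39	6	6	0.33	3.25	0.77	24
V1-Ctrl-10X	0.00	3	0.25	9	3	9	NA	2.00	0.67	9
V6-Ctrl-10X	0.00	1	1.00	6	4	4	NA	3.00	0.00	4
R2-Ctrl-10X	0.08	6	0.16	51	7	7	0.23	3.92	0.72	26
R6-Ctrl-10X	0.10	5	0.19	43	7	7	0.28	3.91	0.68	22
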