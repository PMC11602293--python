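residue	rmsf_low	rmsf_high	delta	conservation	contact
30	0.726	0.749	0.023	8	0
31	0.782	0.822	0.040	9	0
33	0.507	0.569	0.062	8	0
34	0.538	0.619	0.081	9	0
61	1.325	1.215	-0.110	1	0
62	1.186	1.371	0.185	4	0
63	1.018	1.395	0.377	5	0
65	0.515	0.541	0.026	9	0
66	0.620	0.713	0.093	9	0
67	0.526	1.368	0.842	7	0
68	0.701	1.032	0.331	8	0
69	0.651	0.692	0.041	8	0
93	0.718	0.787	0.069	7	0
94	0.704	0.804	0.100	8	0
95	0.734	0.821	0.087	6	0
96	0.918	0.981	0.063	4	1
125	0.441	0.652	0.211	9	0
126	1.347	1.443	0.096	6	1
127	1.046	1.285	0.239	6	0
152	0.579	0.599	0.020	8	0
153	0.634	0.658	0.024	8	0
154	0.526	0.579	0.053	9	1
155	0.887	0.889	0.002	9	0
216	1.047	1.240	0.193	1	0
217	1.329	1.775	0.446	1	0
218	0.746	0.908	0.162	7	0
219	0.471	0.515	0.044	9	0
220	0.577	0.661	0.084	9	0
222	0.888	0.897	0.009	7	1
223	0.596	0.603	0.007	9	0
224	0.529	0.590	0.061	7	0
225	0.462	0.476	0.014	9	0
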