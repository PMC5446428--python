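mirna	presence_fc	presence_cc	presence_gbm	median_fc	median_cc	median_gbm	seed_event	precursor_position	targets_before	targets_after	targets_overlap	novel	snapshot_validated
hsa-mir-598-3p	6	5	0	0.49	0.34	0	yes	62	11	9	0	0	0
hsa-mir-376a-1-5p	6	6	0	11.24	8.43	0	yes	9	131	166	4	0	0
hsa-mir-337-3p	4	1	0	4.21	-	0	yes	66	146	197	11	1	0
hsa-mir-376c-3p	6	5	2	3.72	1.9	-	yes	48	156	192	11	0	0
hsa-mir-1301-3p	6	6	2	7.59	3.94	-	yes	52	230	7	2	1	1
hsa-mir-421	6	6	3	1.40	0.61	0.57	yes	54	271	4	1	0	0
hsa-mir-99b-3p	6	6	2	3.61	1.65	-	yes	47	33	21	0	1	0
hsa-mir-641-5p	6	6	3	5.62	7.08	3.35	yes	18	355	128	11	0	0
hsa-let-7e-3p	4	0	0	2.09	0	0	yes	57	5	3	0	1	0
hsa-mir-1251-5p	4	4	0	11.98	11.87	0	yes	10	58	305	4	1	1
hsa-mir-381-3p	6	6	5	6.87	7.15	3.07	yes	52	638	302	48	0	1
hsa-mir-411-5p	6	6	5	27.57	30.85	5.71	yes	20	64	58	0	0	0
hsa-mir-130a-3p	5	5	0	0.76	0.97	0	yes	56	724	172	27	0	0
hsa-mir-151a-3p	6	6	3	2.87	1.26	0.48	yes	49	76	77	3	0	0
hsa-let-7d-3p	6	4	0	0.70	0.31	0	yes	66	9	1	0	0	0
hsa-mir-27b-3p	5	0	0	0.25	0	0	yes	64	921	8	2	1	0
hsa-mir-301b-3p	5	2	1	1.24	-	-	no	63	NA	NA	NA	1	0
hsa-mir-340-3p	4	0	0	1.19	0	0	no	70	NA	NA	NA	1	0
hsa-mir-377-3p	4	3	0	8.10	4.6	0	no	54	NA	NA	NA	1	0
hsa-mir-539-5p	6	6	0	2.23	1.62	0	no	18	NA	NA	NA	1	0
hsa-mir-889-3p	5	5	0	0.62	0.41	0	no	62	NA	NA	NA	1	0
hsa-mir-99a-5p	6	6	4	3.40	1.44	0.30	no	13	NA	NA	NA	0	0
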