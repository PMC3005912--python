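gene	cluster_index	isoform_id	n_regions	sum_len	protein_len
SYNE1	1	ENSMUSP00000051825	94	4390	8800
SYNE1	1	ENSP00000265368	89	4326	8798
SYNE1	1	ENSP00000308157	88	4275	8750
SYNE1	1	ENSP00000356216	89	4327	8798
SYNE1	1	ENSP00000356220	88	4276	8750
SYNE1	1	ENSP00000356224	89	4372	8798
SYNE1	1	ENSP00000390975	88	4321	8750
SYNE1	1	ENSP00000396024	88	4275	8750
SYNE1	2	ENSMUSP00000093587	9	410	950
SYNE1	2	ENSP00000318783	9	403	983
SYNE1	3	ENSP00000356225	29	1727	3322
SYNE1	4	ENSMUSP00000039440	16	616	1432
ESR2	1	ENSP00000343925	5	243	531
ESR2	1	ENSMUSP00000075932	5	295	550
ESR2	1	ENSMUSP00000106051	5	295	550
ESR2	2	ENSP00000351412	5	244	496
ESR2	2	ENSP00000335551	5	244	496
ESR2	3	ENSMUSP00000098849	5	295	568
AHNAK	1	ENSP00000257247	1	67	150
AHNAK	1	ENSMUSP00000090632	2	120	185
AHNAK	2	ENSP00000367263	6	5716	5891
AHNAK	2	ENSMUSP00000090633	10	5431	5657
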