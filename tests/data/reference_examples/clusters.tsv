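group_id	cluster_index	isoform_id	species	is_anchor	anchor_score
AHNAK	1	ENSMUSP00000090632	mouse	false	
AHNAK	1	ENSP00000257247	human	false	
AHNAK	2	ENSMUSP00000090633	mouse	false	
AHNAK	2	ENSP00000367263	human	false	
ESR2	1	ENSMUSP00000075932	mouse	false	
ESR2	1	ENSMUSP00000106051	mouse	false	
ESR2	1	ENSP00000343925	human	false	
ESR2	2	ENSP00000335551	human	false	
ESR2	2	ENSP00000351412	human	false	
ESR2	3	ENSMUSP00000098849	mouse	false	
SYNE1	1	ENSMUSP00000051825	mouse	false	
SYNE1	1	ENSP00000265368	human	false	
SYNE1	1	ENSP00000308157	human	false	
SYNE1	1	ENSP00000356216	human	false	
SYNE1	1	ENSP00000356220	human	false	
SYNE1	1	ENSP00000356224	human	false	
SYNE1	1	ENSP00000390975	human	false	
SYNE1	1	ENSP00000396024	human	false	
SYNE1	2	ENSMUSP00000093587	mouse	false	
SYNE1	2	ENSP00000318783	human	false	
SYNE1	3	ENSP00000356225	human	false	
SYNE1	4	ENSMUSP00000039440	mouse	false	
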