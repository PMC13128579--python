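dataset	tissue_context	category	n_clones	n_cells
Caushi2021	Lung (NSCLC)	trt	25	1512
Caushi2021	Lung (NSCLC)	nontrt_vdjdb	1332	5833
Hanada2022	Lung (NSCLC)	trt	19	576
Hanada2022	Lung (NSCLC)	nontrt_vdjdb	516	986
Lowery2022	Melanoma, breast, GI	trt	45	378
Lowery2022	Melanoma, breast, GI	nontrt_vdjdb	400	707
Meng2025	PDAC	trt	61	626
Meng2025	PDAC	nontrt_expt	52	1510
Oliveira2021	Melanoma	trt	46	5006
Oliveira2021	Melanoma	nontrt_expt	92	2427
Oliveira2021	Melanoma	nontrt_vdjdb	10	164
Petremand2024	Melanoma	trt	78	1390
Petremand2024	Melanoma	nontrt_expt	96	1172
Petremand2024	Melanoma	nontrt_vdjdb	12	158
Gao2020	Healthy PBMC	nontrt_pbmc	11730	13317
Ogura2022	Healthy + CoV2-experienced PBMC	nontrt_pbmc	819	3226
TenxPBMC	Healthy PBMC	nontrt_pbmc	1132	1168
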