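sample_id	grade	age	sex	survival_days	subtype	purity	depth	spm_count	sim_count	recurrent	hypermutated
3004	IV	70	M	134	CL	89	72	7788	330	0	0
3009	IV	60	M	174	CL	72	75	9037	359	0	0
3013	IV	78	F	122	PN	83	78	8477	308	0	0
3039	IV	38	M	994	CL	98	77	7167	266	0	0
3046	IV	73	M	186	CL	71	74	8587	336	0	0
3048	IV	77	M	279	CL	99	72	9266	431	0	0
3053	IV	64	M	277	MS	64	72	4201	157	0	0
3065	IV	77	M	127	MS	84	86	14666	450	0	0
3071	IV	65	M	309	MS	82	70	9461	386	0	0
3078	IV	51	M	716	MS	68	79	3729	170	0	0
3082	IV	70	F	314	PN	95	89	10122	385	0	0
3086	IV	72	M	444	CL	86	72	5850	373	0	0
3100	IV	73	M	284	CL	95	68	5028	74	0	0
3102	IV	64	F	543	MS	96	75	7456	285	0	0
3104	IV	59	M	585	CL	54	73	9661	347	0	0
3123	IV	64	M	1613	CL	94	79	12224	364	0	0
3137	IV	74	M	1088	MS	46	78	5819	227	0	0
3151	IV	61	M	817	MS	73	67	230968	1562	1	1
3164	IV	68	M	54	PN	91	81	8661	439	0	0
3172	IV	50	M	1352	CL	78	78	4312	164	0	0
3173	IV	73	F	229	MS	51	64	5345	211	0	0
3177	IV	74	F	179	n/a	99	78	10585	522	0	0
3179	IV	63	M	474	CL	64	69	4696	325	1	0
3187	IV	70	M	193	PN	62	73	4481	194	0	0
3189	IV	83	M	218	CL	98	75	7710	444	0	0
3198	IV	60	M	729	PN	75	78	7968	308	0	0
3202	IV	66	M	137	MS	84	67	5361	324	0	0
3206	IV	61	M	767	PN	71	83	4025	246	0	0
3211	IV	72	F	206	CL	61	75	5151	265	0	0
3220	IV	73	F	492	MS	70	79	4447	268	0	0
3233	IV	53	M	809	MS	100	68	1590	189	1	0
3235	IV	56	M	141	MS	94	71	4570	203	0	0
3242	IV	50	M	449	MS	91	85	4336	246	0	0
3243	IV	43	M	1070	PN	41	81	8282	96	1	0
3253	IV	69	M	92	CL	79	78	8079	358	0	0
3266	IV	54	M	571	n/a	85	76	4767	259	0	0
3274	IV	74	M	206	MS	68	69	6447	227	0	0
3279	IV	56	M	333	MS	41	78	6320	64	0	0
3291	IV	60	F	1527	CL	89	79	7782	327	0	0
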