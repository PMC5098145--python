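variable	description	wald_p	cutoff	design	behaviour	hazard_ratio	n_low_risk	n_high_risk
205382_s_at	CFD	0.0003721	8.026	2	onco-like	2.024	302	47
202246_s_at	CDK4	0.0007521	9.05	1	supp-like	1.964	310	39
204451_at	FZD1	0.0008483	6.66	2	onco-like	2.177	55	294
201947_s_at	CCT2	0.0009464	10.805	2	onco-like	2.003	312	37
205959_at	MMP13	0.0011793	6.618	2	onco-like	1.606	146	203
201954_at	ARPC1B	0.0015679	9.175	2	onco-like	1.617	245	104
age	age	0.0015858	67.0	2	onco-like	1.641	258	91
201615_x_at	CALD1	0.0016123	7.976	2	onco-like	1.917	63	286
204464_s_at	EDNRA	0.0019353	8.037	2	onco-like	1.845	311	38
208944_at	TGFBR2	0.0021252	8.281	2	onco-like	1.565	161	188
203968_s_at	CDC6	0.0021869	6.108	1	supp-like	2.153	325	24
209026_x_at	TUBB	0.0022915	10.051	1	supp-like	2.031	322	27
201774_s_at	NCAPD2	0.0027595	8.598	2	onco-like	2.401	324	25
212239_at	PIK3R1	0.0028506	7.992	2	onco-like	1.535	195	154
203131_at	PDGFRA	0.0034062	8.876	2	onco-like	1.678	283	66
212063_at	CD44	0.0034184	8.845	1	supp-like	1.574	125	224
212782_x_at	POLR2J	0.0034369	10.432	2	onco-like	1.615	278	71
214144_at	POLR2D	0.0034777	7.255	1	supp-like	1.657	90	259
219588_s_at	NCAPG2	0.0042218	8.342	1	supp-like	1.507	185	164
209960_at	HGF	0.0043267	6.522	2	onco-like	1.764	310	39
212294_at	GNG12	0.0043607	9.312	2	onco-like	1.614	283	66
207822_at	FGFR1	0.0050334	6.083	2	onco-like	1.865	62	287
204441_s_at	POLA2	0.0052135	7.167	1	supp-like	1.511	150	199
216598_s_at	CCL2	0.0062289	6.453	2	onco-like	2.101	29	320
202107_s_at	MCM2	0.0069779	8.671	1	supp-like	1.484	232	117
202202_s_at	LAMA4	0.0076547	8.863	2	onco-like	1.893	318	31
215076_s_at	COL3A1	0.0080398	11.322	2	onco-like	1.504	250	99
210845_s_at	PLAUR	0.0082985	7.446	2	onco-like	1.555	93	256
201697_s_at	DNMT1	0.0088655	9.143	1	supp-like	1.47	148	201
202877_s_at	CD93	0.0090467	6.844	2	onco-like	1.675	60	289
203323_at	CAV2	0.0103597	7.806	2	onco-like	1.442	204	145
221559_s_at	MIS12	0.0109485	7.822	1	supp-like	1.471	227	122
208778_s_at	TCP1	0.0110947	9.455	2	onco-like	1.452	142	207
201091_s_at	CBX3	0.0120077	9.928	1	supp-like	1.701	65	284
205393_s_at	CHEK1	0.0120697	6.128	1	supp-like	1.975	328	21
200931_s_at	VCL	0.0125254	9.888	2	onco-like	2.471	22	327
212949_at	NCAPH	0.0129085	7.163	2	onco-like	1.434	214	135
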