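name	model_source	area_A	area_B	ab	lambda_obs	lambda_pred
AncVertebrate-361	AMBER	36.033	68.313	0.527	361	362
AncVertebrate-361	SWISS	32.057	59.109	0.542	361
Zebra finch-359	AMBER	34.166	65.783	0.519	359	359
Zebra finch-359	SWISS	36.937	64.031	0.577	359
Budgerigar-363	AMBER	32.684	64.454	0.507	363	360
Budgerigar-363	SWISS	35.072	65.602	0.535	363
AncBird-393	AMBER	28.598	67.945	0.421	393	399
AncBird-393	SWISS	33.396	67.758	0.493	393
Human-414	AMBER	28.332	69.781	0.406	414	409
Human-414	SWISS	31.422	60.574	0.519	414
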