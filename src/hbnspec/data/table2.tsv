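background	mutation	d_lambda	d_ab	printed_class	background_lambda	target	target_lambda	nd	excluded	note
AncVertebrate-361	F86 deletion	-43	-0.004	III	361	scabbardfish-423	423	0	0
AncEuteleost-364	F86 deletion				364	scabbardfish-423	423	1	0	mutant structurally unstable; lambda_max unmeasurable
Lampfish-371	F86 deletion	-15	0.003	III	371	scabbardfish-423	423	0	0
bfin killifish-355	F86 deletion	6	0.028	III	355	scabbardfish-423	423	0	0
scabbardfish-423	F86 deletion	2	0.001	I	423	AncEuteleost-364	364	0	0	printed mutation string; elsewhere named ins(F86)
AncBoreotheria-360	F86L	-54	-0.034	III	360	Human-414	414	0	0
Human-414	L86F	22	-0.005	III	414	AncBoreotheria-360	360	0	0
AncAmphibian-359	F86M	-62	0.036	III	359	Frog-423	423	0	0
Frog-423	M86F	39	-0.042	III	423	AncAmphibian-359	359	0	0
AncBoreotheria-360	F86Y	-30	0.020	III	360	Bovine-438	438	0	0
Bovine-438	Y86F	7	-0.018	III	438	AncBoreotheria-360	360	0	0
AncBoreotheria-360	F86Y	-32	0.004	III	360	Squirrel-440	440	0	0	d_ab garbled in source text; transcribed as 0.004
Squirrel-440	Y86F	4	-0.004	II	440	AncBoreotheria-360	360	0	0
AncMammal-359	F86Y	-4	-0.001	I	359	Wallaby-420	420	0	0
Wallaby-420	Y86F	2	0.001	I	420	AncMammal-359	359	0	0
AncEutheria-360	F86S	-45	0.018	III	360	Elephant-419	419	0	0
AncEutheria-360	F86S/T93I	-4	0.015	II	360	Elephant-419	419	0	0
AncEutheria-360	F86S/T93I/L116V	-11	0.005	III	360	Elephant-419	419	0	0
Elephant-419	S86F	7	-0.009	III	419	AncEutheria-360	360	0	0
Elephant-419	S86F/I93T	-1	-0.019	II	419	AncEutheria-360	360	0	0
Elephant-419	S86F/I93T/V116L	0	0.005	II	419	AncEutheria-360	360	0	0
AncSauropsid-360	F49V/F86S/L116V/S118A	0	-0.001	I	360	AncBird-393	393	0	0
AncBird-393	V49F/S86F/V116L/A118S	0	0.001	I	393	AncSauropsid-360	360	0	0
AncAmphibian-359	F86M/V91I/T93P/V109A/E113D/L116V/S118T	-2	0.002	I	359	Frog-423	423	0	0
Frog-423	M86F/I91V/P93T/A109V/D113E/V116L/T118T	-4	0.001	I	423	AncAmphibian-359	359	0	0
AncBoreotheria-360	F46T/F49L/T52F/F86L/T93P/A114G/S118T	-2	0.01	1	360	Human-414	414	0	1	printed class 1 with d_ab 0.01 inconsistent with the 0.002 rule
Human-414	T46F/L49F/F52T/L86F/P93T/G114A/T118S	0	-0.001	1	414	AncBoreotheria-360	360	0	1	printed class 1; likely typesetting artifact
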