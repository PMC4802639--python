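background	mutations	lambda	theta_printed	theta_reverse_label	theta_reverse_printed
Elephant-419		419
Elephant-419	S86F	367	-52	F86S	51
Elephant-419	I93T	413	-6	T93I	0
Elephant-419	V116L	416	-3	L116V	-1
Elephant-419	S86F/I93T	359	-2	F86S/T93I	5
Elephant-419	S86F/V116L	360	-4	F86S/L116V	3
Elephant-419	I93T/V116L	411	1	T93I/L116V	8
Elephant-419	S86F/I93T/V116L	360	7	F86S/T93I/L116V	-7
AncEutheria-360		360
AncEutheria-360	F86S	374	14
AncEutheria-360	T93I	360	0
AncEutheria-360	L116V	359	-1
AncEutheria-360	F86S/T93I	415	41
AncEutheria-360	F86S/L116V	398	25
AncEutheria-360	T93I/L116V	360	1
AncEutheria-360	F86S/T93I/L116V	410	-30
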