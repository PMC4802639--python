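gene_a	gene_b	time_my
scabbardfish-423	tilapia-360	114
frog-423	salamander-356	298
chicken-415	zebra finch-359	102
human-414	mouse-359	98
bovine-438	mouse-359	98
squirrel-440	mouse-359	98
elephant-419	mouse-359	105
wallaby-420	dunnart-363	62
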