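name	lambda	kind
AncVertebrate-361	361	ancestral
AncEuteleost-364	364	ancestral
AncTetrapod-359	359	ancestral
AncAmphibian-359	359	ancestral
AncAmniote-359	359	ancestral
AncSauropsid-360	360	ancestral
AncBird-393	393	ancestral
AncMammal-359	359	ancestral
AncEutheria-360	360	ancestral
AncBoreotheria-360	360	ancestral
scabbardfish-423	423	present
tilapia-360	360	present
goldfish-360	360	present
lampfish-371	371	present
bfin killifish-355	355	present
frog-423	423	present
salamander-356	356	present
chameleon-359	359	present
chicken-415	415	present
zebra finch-359	359	present
pigeon-393	393	present
budgerigar-363	363	present
canary-366	366	present
human-414	414	present
mouse-359	359	present
bovine-438	438	present
squirrel-440	440	present
elephant-419	419	present
wallaby-420	420	present
dunnart-363	363	present
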