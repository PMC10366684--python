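gene	role	endogenous_length_bp	linker	start_codon
eef-1A.1	control	579	aaaagcaggctaaaa	ATG
mex-5	control	536	aaaagcaggctaaaa	ATG
his-61	candidate	327	aaaagcaggctaaaa	ATG
his-64	candidate	254	aaaagcaggctaaaa	ATG
hil-4	candidate	612	aaaagcaggctaaaa	ATG
rla-0	candidate	735	aaaagcaggctaaaa	ATG
rpl-7A	candidate	289	aaaagcaggctaaaa	ATG
Y37E3.8	candidate	748	aaaagcaggctaaaa	ATG
klp-19	candidate	308	aaaagcaggctaaaa	ATG
his-68	candidate	368	aaaagcaggctaaaa	ATG
W05F2.3	candidate	301	aaaagcaggctaaaa	ATG
spn-4	candidate	588	aaaagcaggctaaaa	ATG
pos-1	candidate	618	aaaagcaggctaaaa	ATG
Y75B12B.1	candidate	667	aaaagcaggctaaaa	ATG
puf-5	candidate	580	aaaagcaggctaaaa	ATG
mei-2	candidate	306	aaaagcaggctaaaa	ATG
mesp-1	candidate	519	aaaagcaggctaaaa	ATG
puf-11	candidate	880	aaaagcaggctaaaa	ATG
F23A7.8	candidate	560	aaaagcaggctaaaa	ATG
clec-87	candidate	415	aaaagcaggctaaaa	ATG
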