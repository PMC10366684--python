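strain	n_events
N2	64
mex-5	179
klp-19	134
his-68	156
W05F2.3	195
spn-4	160
pos-1	75
mei-2	238
Y75B12B.1	103
puf-5	104
mesp-1	91
puf-11	109
F23A7.8	54
clec-87	75
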