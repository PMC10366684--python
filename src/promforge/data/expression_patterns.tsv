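gene	pattern
his-61	somatic_and_germline
his-64	somatic_and_germline
hil-4	somatic_and_germline
rla-0	somatic_and_germline
rpl-7A	somatic_and_germline
Y37E3.8	somatic_and_germline
puf-11	none
F23A7.8	none
clec-87	none
klp-19	germline_specific
his-68	germline_specific
W05F2.3	germline_specific
spn-4	germline_specific
pos-1	germline_specific
Y75B12B.1	germline_specific
puf-5	germline_specific
mei-2	germline_specific
mesp-1	germline_specific
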