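{
 "note": "curated reference promoter set; checksums guard transcription integrity",
 "sha256": {
  "reference_promoters.fasta": "296b30764e722441bb3522dc8399a539f521959044b772525095173346b944f4",
  "reference_promoters.tsv": "df331d75630fabf7ce0f7ce1ba2e82be1ca83205f48d1cbbe4f7ba2140b7ff2b",
  "expression_patterns.tsv": "aff6edd9d5b5837d4c9d85b13705ae3acc394a1bc1c6a998cadacb80a2657c09",
  "copas_event_counts.tsv": "a63bb8c012641415f0d6c8b1b0aa9699847d7ca26dd326721d5727b8ecb21ef0"
 }
}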