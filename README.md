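# promforge

A tested pipeline for designing and quantifying short germline-specific
promoters in *C. elegans*:

1. **selection** — rank genes by germline expression specificity (TPM fraction
   over the five-tissue panel germline / neurons / intestine / hypodermis /
   muscle) and extract candidate promoter regions from genome annotation
   (start codon of the candidate back to the proximal coding boundary of the
   nearest upstream protein-coding gene, ≤ 1 kb).
2. **domestication** — make parts synthesis- and Golden-Gate-ready: minimal
   single-base substitutions to remove homopolymer runs ≥ 10 bp and BsaI
   (`GGTCTC`) sites on either strand, append the fixed 15 bp cloning linker
   (`aaaagcaggct` + `aaaa`), and add outward-reading donor flanks with 4-nt
   overhangs.
3. **assembly** — in silico Golden Gate: type-IIS digestion with standard
   N1/N5 cut geometry, overhang-graph ligation returning the unique scarless
   circular product (ambiguity raises rather than guessing), construct
   verification, and an injection-mix recipe helper.
4. **quantification** — large-particle cytometry gating (TOF within
   [1500, 1800] inclusive, extinction below 35,000 strict), per-strain green
   mean ± SEM, baseline subtraction and ratio normalization against a
   non-transgenic control, blinded visual-score summaries, and
   expression-pattern census.
5. **synthetic_data** — ground-truthed generators for every input: annotated
   toy genomes with controllable intergenic gaps, TPM tables with planted
   germline enrichment, sequences with planted violations, mixed-stage
   cytometry event tables with planted fold-changes, and a toy destination
   vector.

A curated 20-entry reference promoter set (18 candidates + 2 controls, each
ending in the 15 bp linker) ships under `src/promforge/data/` together with
its expression-pattern table and per-strain cytometry event counts; SHA-256
checksums guard the transcription.

## CLI

```sh
promforge select --expression expr.tsv --gff genes.gff3 \
    --min-tpm 100 --min-fraction 0.4 --max-length 1000 --out candidates.tsv

promforge domesticate --in parts.fa --run-threshold 10 \
    --overhangs GGAG,aaaa --out parts.domesticated.fa --edits edits.tsv

promforge assemble --parts parts.fa --dest destination.gb --out construct.gb

promforge mix --components mix.tsv

promforge quantify --events events.csv --control N2 \
    --tof 1500:1800 --ext-max 35000 --relative ratio --out summary.tsv

promforge simulate {genome|expression|sequences|copas} --seed 1 --out DIR
```

Every `simulate` output directory contains a `truth.json` recording exactly
what was planted.

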