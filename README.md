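# utrsat

In-silico saturation mutagenesis and upstream-ORF annotation of transcript
5'UTRs.

## The problem

Variants in 5' untranslated regions can silence a gene without touching its
protein sequence: a single substitution may create an upstream translation
initiation site (uTIS) — a canonical AUG or one of the nine near-cognate
codons one nucleotide away from AUG (CUG, GUG, UUG, ACG, AAG, AGG, AUA, AUC,
AUU) — whose upstream open reading frame (upORF) competes with the main ORF
and reduces protein output. The motivating case is *ENG* (Endoglin), where
5'UTR variants creating upORFs that overlap the coding sequence cause
Hereditary Hemorrhagic Telangiectasia. `utrsat` is for geneticists and
variant-curation pipelines that need an exhaustive, reproducible catalog of
every possible 5'UTR SNV and its upORF consequences for a transcript of
interest.

## What it computes

Working entirely in HGVS coding coordinates (c.1 = A of the main AUG, no
position zero), the annotator examines, for each SNV, the three triplet
windows that overlap it — one per reading frame — and reports:

* **uTIS_created** — the window gains a new TIS identity (none → TIS,
  near-cognate → AUG, or near-cognate → different near-cognate; a change
  away from AUG is a loss and is not annotated). The new uTIS is extended
  codon-by-codon to its first in-frame stop and typed:
  - **uORF** — stop entirely within the 5'UTR;
  - **uoORF** — out-of-frame with the CDS, stop inside the CDS;
  - **eCDS** — in frame with the CDS, running to the main stop codon
    (an N-terminally elongated protein).
* **uStop_created** — the window gains TAA/TAG/TGA in frame with an
  existing upstream uTIS, shortening that uTIS's ORF or carving a new one.
* **uStop_deleted** — a stop terminating an existing upORF is destroyed
  (stop → different stop does not count), elongating the ORF to the next
  in-frame stop.

Every record carries the Kozak 7-mer of the uTIS read from the
variant-applied sequence and its strength: **strong** (purine at −3 and G
at +4), **moderate** (exactly one of the two), **weak** (neither).
The length of an upORF is counted from the first uTIS base through the last
stop-codon base; a stop's "position" is its first base.

Because no real download is required anywhere, the package ships
`eng_like_transcript()`, a *synthetic* ENG-like transcript: a 303-nt 5'UTR
and 1977-nt CDS whose bases are pinned wherever published ENG variant
annotations determine them (the contexts of the 14 known uTIS-creating
variants, the upstream stops TGA c.-166 / TAA c.-34, and the first
out-of-frame CDS stops at c.90 and c.125). It reproduces the per-variant
annotation surface of the real transcript exactly; whole-catalog totals
differ because the unpinned bases are filler.

## Worked example

```python
from utrsat import eng_like_transcript, make_snv, annotate_variant

t = eng_like_transcript()
(rec,) = annotate_variant(t, make_snv(t, -76, "T"))
print(f"{rec.snv.hgvs_c}: {rec.consequence}")
print(f"  created TIS : {rec.created_tis.codon} at c.{rec.created_tis.c_start}")
print(f"  upORF       : {rec.uporf.orf_type}, stop at c.{rec.uporf.stop_c_start}, "
      f"{rec.uporf.length_nt} nt")
print(f"  Kozak       : {rec.kozak.sevenmer} ({rec.kozak.strength})")
```

prints

```
c.-76C>T: uTIS_created
  created TIS : CTG at c.-77
  upORF       : uoORF, stop at c.125, 204 nt
  Kozak       : ACGCTGG (strong)
```

i.e. the substitution turns CCG into an upstream CUG at c.-77, in frame
with the stop codon whose first base is c.125, creating an overlapping
upORF of 77 + 127 = 204 nt inside a strong Kozak context — the hallmark
annotation of this pathogenic *ENG* variant class.

The same pipeline is available from the shell:

```bash
utrsat saturate --transcript tx.fa --sidecar tx.yaml --out all_snvs.vcf
utrsat annotate --transcript tx.fa --sidecar tx.yaml --out catalog   # catalog.tsv + catalog.vcf
utrsat annotate --transcript tx.fa --sidecar tx.yaml --vcf-in observed.vcf --out observed
utrsat selftest --n 100 --seed 0
```

`annotate` logs the summary tallies (n_snvs, n_annotated, pure/multi
consequence classes, upORF type counts, per-stop-position tallies) as JSON.

## Layout

* `utrsat.transcript` — transcript model, validation, HGVS c. arithmetic
* `utrsat.saturation` — SNV enumeration, transcript-space VCF I/O
* `utrsat.orf` — uTIS scanning, ORF extension, uORF/uoORF/eCDS typing
* `utrsat.kozak` — Kozak context extraction and strength rule
* `utrsat.annotate` — per-variant delta annotation, catalog, TSV/VCF output
* `utrsat.synthetic` — toy generator, ENG-like stand-in, brute-force oracle
* `utrsat.cli` — `utrsat` command group

See `docs/methods.md` for the model, its assumptions and design choices.
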