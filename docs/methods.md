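# Methods

## Coordinate model

All computation happens in transcript space. A transcript is the
concatenation 5'UTR + CDS (+ optional 3'UTR) with HGVS coding coordinates:
c.1 is the A of the main AUG, c.-1 the base immediately 5' of it, and there
is no position zero. Internally positions map to zero-based offsets
(`index = L + c − 1` for c > 0, `L + c` for c < 0, L = UTR length), and all
interval lengths are computed in offset space so the no-zero rule can never
be double-applied. Genomic coordinates, strand handling and multi-exon
models are out of scope; inputs are a cDNA/mRNA record plus the CDS span.

Two conventions fix every reported number and are applied consistently:

* a stop codon's *position* is the coordinate of its **first** base;
* an upORF's length runs from the first uTIS base **through the last stop
  base** (stop included), hence is always a multiple of 3. A uTIS at c.−x
  in frame with a stop whose first base is c.s (s > 0) therefore yields an
  ORF of x + s + 2 nt — e.g. 77 + 127 = 204 for a uTIS at c.-77 with its
  stop at c.125.

Where sources interchangeably describe a uORF as "ending at c.-34" or
"with the stop at c.-33", the first-base convention (c.-34) is adopted.

## TIS model

Canonical AUG plus the nine single-mismatch near-cognate codons (CUG, GUG,
UUG, ACG, AAG, AGG, AUA, AUC, AUU). `tis_mode` selects canonical-only,
near-cognate-only, or both (default). Each uTIS is treated independently —
no leaky-scanning or re-initiation model, no minimum ORF length, and no
translation-efficiency prediction (external KSS/PreTIS scores are accepted
as pass-through columns only, never recomputed).

**Creation rule.** An SNV creates a uTIS in a window when the ALT codon is
a TIS of the chosen mode, differs from the REF codon, and the REF codon is
not AUG. This deliberately counts near-cognate → AUG upgrades *and*
near-cognate → different-near-cognate identity changes as creations (both
occur among the curated ENG variants: AUA→AUG at c.-35, and AUC→AUA at
c.-289 produced by c.-287C>A), while a change away from AUG is a TIS loss,
which — like all TIS losses — is not annotated. A variant that destroys one
TIS window while creating another is reported for the gain only.

## Stop events

A window gaining TAA/TAG/TGA where REF had none is a stop creation; it is
reported once per upstream in-frame reference uTIS whose variant-sequence
ORF terminates exactly at the new stop (no intervening in-frame stop). If
that uTIS's reference ORF ended at a downstream stop the event is a
*shortening*; if it previously ran to the main stop the new stop defines a
new upORF. A created stop with no linked upstream uTIS alters no upORF and
is silent unless `report_orphan_stops` is set. A window losing a stop
elongates every reference ORF that terminated there, re-extending from the
same uTIS on the variant sequence; a stop mutated into a different stop
codon (e.g. TAA→TGA) is neither a gain nor a loss. Of the nine single-base
changes of a stop codon, TAA has exactly 7 deleters and TAG/TGA exactly 8 —
the two/one remaining changes reach another stop codon.

Because an upstream in-frame uTIS always ends at least three bases before
the changed window, stop events can never sit inside their linked uTIS
triplet; the linkage is therefore stable under the variant itself.

## ORF typing

The walk from a uTIS proceeds in steps of three through utr5+cds(+utr3)
until the first stop codon; windows must fit entirely inside the sequence.
Classification is stop-position-first: a stop entirely within the 5'UTR
gives a uORF (this includes the degenerate case of a frame-0 uTIS meeting a
frame-0 UTR stop); otherwise an in-frame uTIS necessarily reaches the main
stop (the CDS has no internal in-frame stop) and gives an eCDS; any other
outcome — a stop inside the CDS or straddling the UTR/CDS junction — is an
overlapping uoORF. A walk that finds no stop ("no-stop") defines no upORF;
a created uTIS in that situation is still recorded, with an empty ORF slot.

## Kozak contexts

The 7-mer spans −3..−1, the TIS triplet, and +4. Strength: strong = purine
at −3 and G at +4; moderate = exactly one; weak = neither. The rule applies
identically to near-cognate TIS, and the context of a variant-created TIS
is read from the variant-applied sequence, since the variant can sit inside
its own 7-mer (as the c.-76C>T CUG does). A TIS closer than 3 nt to the
transcript start gets an N-padded 7-mer, is flagged undetermined, and falls
through the classifier as weak.

## Windowed delta vs brute force

`annotate_variant` re-examines only the ≤3 windows overlapping the variant.
Its correctness rests on the argument that a single substitution can change
codon content only in those windows, and changes ORF walks only at or
through them. The claim is not trusted: `synthetic.brute_force_annotate`
recomputes the full TIS/stop landscapes of REF and ALT with its own
scanning and walking code (no shared ORF logic) and diffs them under the
same event semantics, and the suite asserts record-level equality over 100
seeded random transcripts × all of their 5'UTR SNVs, plus a
hypothesis-driven sweep over tiny adversarial transcripts (UTRs down to
1 nt, all three TIS modes, orphan-stop reporting on and off).

## Catalog summary semantics

Per-SNV consequence classes: an annotated SNV with exactly one distinct
class is counted pure; with two or more, multi-consequence. `n_uporfs`
counts distinct (SNV, resulting ORF) pairs over all records;
`n_uporfs_uTIS_created` restricts to TIS-creation records, and equals
`n_uORF + n_uoORF + n_eCDS` by construction. Per-stop-position tallies are
keyed `type@c.pos` with `eCDS@main` for the main stop.

## The synthetic data

`random_transcript(ToySpec)` emulates only the structural facts the
annotator depends on: a valid CDS (ATG start, single terminal stop, no
internal in-frame stop, rejection-sampled), an ACGT-uniform UTR of chosen
length, optional planted motifs re-validated after insertion. It does not
emulate real base composition, GC structure, or UTR length distributions,
so passing tests demonstrate algorithmic correctness, not calibration to
genomic sequence statistics.

`eng_like_transcript()` is a synthetic stand-in for the ENG MANE transcript
(ENST00000373203.9), which cannot be bundled. Its construction, in order:

1. 303-nt UTR of seeded-uniform filler; ~90 bases overwritten with the
   reference bases that published variant annotations pin down (each of the
   14 curated uTIS-creating variants fixes its ALT 7-mer context and REF
   codon; overlapping rows cross-validate each other and force the stop
   identities TGA at c.-166 and TAA at c.-34);
2. four near-cognate uTIS planted in frame 2 (ACG c.-298, CTG c.-262, GTG
   c.-157, ACG c.-121) to emulate the naturally occurring uORFs ending at
   the two UTR stops; the frame-1 near-cognates at c.-182/-167/-35 come
   with the pinned rows;
3. a 659-codon CDS of non-stop codons with TGA planted at c.90 (first
   frame-2 stop) and c.125 (first frame-1 stop);
4. a repair pass banning stop codons from every other out-of-frame window
   in the UTR and in the CDS upstream of c.90/c.125 (setting one free base
   per offending window to C, which occurs in no stop codon, so repairs
   cannot cascade); the main start/stop codons and all pinned bases are
   untouchable.

Everything the pinned landscape determines — the 14 variant-created upORFs
with their exact sizes, shared c.125 stop, Kozak 7-mers and strength
classes, the elongation targets of stop deletions (c.-166→c.-34,
c.-34→c.90), and the restriction of created-ORF stops to
{c.-166, c.-34, c.90, c.125, main} — holds for every seed and is asserted
exactly in the tests. Whole-catalog totals (counts of annotated SNVs and
ORFs per type) depend on the filler bases and are *not* expected to match
the true transcript; the acceptance test that asserts the true-transcript
totals documents this limit and fails on the stand-in by design. No
generator parameter was tuned toward those totals.

## Numerical and design choices

* Saturation order is position-major, then ALT base A<C<G<T; one VCF record
  per SNV, POS = 1-based transcript offset, contig = transcript id.
* The c.125 and c.90 stops are written as TGA in the stand-in; their
  identities are not determined by the pinned rows (the choice affects only
  deleter counts of those stops, which no exact check depends on).
* Problem sizes: the equivalence sweep uses 100 transcripts with UTR
  lengths 20–120 nt and 6–20 CDS codons (≈23k SNV annotations, a few
  seconds), chosen to cover all window-edge and frame cases many times over
  while keeping the default test run fast.
* Deterministic throughout: all randomness flows from explicit seeds.

## Known limitations

* Single-nucleotide substitutions only; no MNVs or indels.
* Per-uTIS accounting ignores ribosome scanning context (an upstream AUG in
  a strong context does not suppress the annotation of a downstream one).
* TIS losses and Kozak-strength *changes* at pre-existing TIS are not
  annotated.
* The ENG-like stand-in supports exact per-variant checks but not
  whole-catalog totals; users with access to the genuine transcript record
  can load it with `load_transcript` and build the full catalog directly.
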