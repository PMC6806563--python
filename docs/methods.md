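# Methods

## Problem and model

Cytosine base editors (CBEs) are CRISPR–deaminase fusions that convert C•G
base pairs to T•A inside a short *editing window* of the protospacer, without
double-strand breaks. Whether a given single-nucleotide variant is reachable
by a given editor is a purely geometric question: does any protospacer
placement exist that (i) puts the target cytosine inside the editor's window
and (ii) carries a PAM matching the editor's IUPAC motif on the correct side
of the protospacer?

`bescan` models an editor as the tuple (PAM pattern, PAM side, spacer length
L, window `[w_start, w_end]`). All protospacer positions are counted 5'→3'
along the protospacer with position 1 at the 5'-most base. This one
convention reproduces both of the field's numbering habits: for a 3'-PAM
(Cas9-family) editor position 1 is PAM-distal, while for a 5'-PAM
(Cpf1/Cas12a-family) editor position 1 is PAM-proximal. The boundary tests in
the suite (`test_window_numbering_convention_at_boundaries`) pin this down
for both families.

Two use cases are distinguished per variant:

* **create** (C>T or G>A variants): the editable base is the *reference*
  allele's C. If the reference is C the protospacer lies on the plus strand;
  if it is G, the C sits on the minus strand.
* **correct** (T>C or A>G variants): the patient carries the C. The alt
  allele is substituted into the reference flank *before* guide search, and
  the strand is chosen so the substituted base reads C.

A placement's *bystanders* are the other cytosines inside the window **on the
target strand** — the deaminase acts on the displaced strand only, so window
guanines are not at risk. A placement with no bystander is *preferential*:
the target is the only editable base, and clean editing is expected. A
variant counts as preferentially targetable by an editor if **any** of its
placements is bystander-free (a `preferential_mode` of "all" was considered;
"any" is used because one clean guide suffices in practice).

## Enumeration algorithm and its oracle

For a target C at index `t` of the target-strand view `s` of the flank, the
placement putting the C at window position `p` is unique: protospacer
`s[t-(p-1) : t-(p-1)+L]`, PAM immediately 3' (or 5') of it. The engine
therefore loops over `p ∈ [w_start, w_end]` only — at most `w_end - w_start
+ 1` candidates, emitted in ascending window order. Placements that run out
of the flank are skipped; placements whose protospacer or PAM contains a
non-ACGT base are rejected and tallied in a diagnostics counter; a PAM with
an ambiguous genome base never matches, whatever the pattern allows.

The package ships a second, deliberately naive enumerator
(`bescan.oracle`) that shares no code with the engine: it slides **every**
protospacer start across the sequence and re-derives window membership and
PAM match from first principles, with its own complement table and IUPAC
sets. Synthetic fixtures record ground truth with the oracle, and the test
suite compares the engine against it placement-for-placement on >1,000
random sequence × editor cases. Useful consequences checked as properties:
an all-N PAM with window `[1, L]` yields exactly L candidates; widening the
window never loses candidates; specialising any PAM position N→G never gains
one; every verdict is invariant under reverse-complementing the input.

## The editor panel

The default panel of 20 CBE geometries lives in `src/bescan/data/editors.tsv`
— a human-editable file that is the single source of truth; each entry
carries the primary citation its PAM/window/spacer values were transcribed
from (Komor 2016; Nishida 2016; Kim 2017; Wang 2017, 2018; Koblan 2018;
Hu 2018; Jiang 2018; Li 2018). Spacer length is per-editor (Cas9-family 20
nt, SaCas9 21 nt, Cpf1-family 23 nt). Custom editors are validated by the
same invariants (`1 ≤ w_start ≤ w_end ≤ L`, non-empty IUPAC PAM). Panel
verdicts combine by union (targetable by ≥1 selected editor — the default)
or intersection (by all).

Editor *efficiency* is deliberately out of scope: the panel captures
geometry only, and no attempt is made to rank editors beyond
targetable/preferential.

## Variant filtering

ClinVar-style tables are filtered by: type = "single nucleotide variant" →
clinical significance = "pathogenic" (exact label, case-insensitive;
compound labels like "Pathogenic/Likely pathogenic" are excluded by default
and admitted with `exact_significance=False`) → assembly = GRCh38 →
deduplication by (chrom, pos, ref, alt). Per-step row counts are logged.
Edit class is assigned by the name-substring rule (C>T/G>A vs T>C/A>G), with
an allele-based fallback for plain VCF input that has no ClinVar-style name;
a name matching both families is ambiguous and dropped with a warning. A
disagreement between the stated reference allele and the genome FASTA is a
hard error, never a warning — silent coordinate drift is the worst failure
mode of a guide designer.

The default flank is 30 nt each side of the SNV; it is widened automatically
(with a log message) whenever the panel's longest spacer+PAM footprint needs
more. Coordinates are 1-based inclusive at every interface (VCF/ClinVar
convention) and 0-based half-open internally.

## Amplicon quantification

From aligned amplicon reads (SAM, or an equivalent plain-text pileup):

* **indel frequency** = reads whose alignment contains ≥1 inserted or
  deleted nucleotide overlapping the region / **mapped** reads;
* **substitution frequency** = reads carrying the substitution / **total**
  reads (the denominators differ deliberately; a `denominator="mapped"`
  switch is provided);
* **product purity** = C→T reads / (C→T + C→A + C→G) at the target, i.e.
  the intended outcome among all edited outcomes. The alternative
  "C→T among all reads" is available via `denominator="total"`. With zero
  edited reads purity is NaN — an explicit undefined marker that propagates,
  never a silent 0;
* **normalisation**: per-editor frequencies divided by a reference editor's
  value, ×100 (the reference editor reads 100%); invariant under rescaling
  all inputs.
* **one-tailed Wilcoxon rank-sum test**: exact by enumeration of all
  C(n, n1) rank assignments for combined n ≤ 20 without ties, else the
  normal approximation with midranks, tie-corrected variance and 0.5
  continuity correction. The approximate branch is cross-checked against
  `scipy.stats.mannwhitneyu` to 1e-9 in the tests; the exact branch against
  scipy's exact method and the closed case p({1,2,3} vs {4,5,6}, less) =
  1/20.

## Synthetic data generator

The generator emulates the shapes of the real inputs, with ground truth
recorded at construction:

* random genomes with i.i.d. bases at a requested GC fraction (default 0.45,
  roughly mammalian);
* ClinVar-like tables with per-category row counts chosen exactly
  (pathogenic create/correct/other SNVs, likely-pathogenic, compound-label,
  benign, indel, wrong-assembly rows), so filter recovery can be asserted
  exactly;
* planted SNV cohorts (default mix 50% create / 50% correct) whose
  per-editor targetable/preferential flags come from the brute-force oracle,
  not from the engine under test;
* amplicon read sets with planted editing rate, C→T purity and 1-bp indel
  rate. The defaults used throughout (editing 0.30, purity 0.90, indel 0.05,
  10,000 reads) are typical of efficient CBE experiments. The indel and the
  substitution are drawn **independently** per read, and the indel is placed
  immediately 3' of the target (overlapping the window, never deleting the
  target base): this keeps the marginal substitution frequency equal to the
  planted editing rate, so estimates are compared directly against the
  planted parameters. All randomness flows from one integer seed per
  artefact; the same seed reproduces files byte-for-byte.

What the generator does **not** emulate: real sequencing error profiles,
base-quality variation, mappability, chromatin context, real ClinVar label
diversity, or linked variants. Passing tests therefore demonstrate the
correctness of the geometry, filtering and counting logic — not editing
efficiency or clinical utility on real data.

## Problem sizes and numerical choices

The suite and the acceptance computations use a 2×20 kb genome with a
300-variant cohort, 1,000 oracle-comparison cases, and 10,000 simulated
reads; these sizes give three-significant-figure stability of the reported
fractions while keeping the whole suite in seconds. Recovery assertions use
3 binomial standard errors at the planted rate. Ties in guide ordering
cannot arise (one placement per window position); multiple placements for
one variant/editor are all reported, with a `--first-only` CLI flag that
keeps the smallest window position (tie-broken by leftmost protospacer
start) for terse output.

## Known limitations

* Targetability is geometric; no efficiency, off-target, or chromatin model.
* Indels and multi-allelic variants are out of scope; liftover between
  assemblies is not provided.
* The GRCh38-scale editability census of all pathogenic ClinVar SNVs
  requires the real ClinVar snapshot and reference genome, which are not
  bundled; the package reproduces the pipeline, not that census.
* Adenine base editors are treated only implicitly (a T>C variant's C is an
  ordinary correction target); ABE window modelling is not attempted.
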