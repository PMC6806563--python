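# bescan

Strand-aware gRNA design and targetability prediction for cytosine base
editors (CBEs), with ClinVar-style pathogenic-SNV filtering and amplicon
editing-outcome quantification.

CBEs convert C•G to T•A inside a short *editing window* of the protospacer,
making them a tool both for **creating** pathogenic C>T (G>A) variants to
model disease and for **correcting** pathogenic T>C (A>G) alleles, whose
patient base reads C. Whether a particular SNV is reachable is a geometric
question: for an editor with spacer length L, editing window
[w<sub>start</sub>, w<sub>end</sub>] (protospacer positions counted 5'→3',
position 1 at the 5'-most base) and a PAM motif on a fixed side of the
protospacer, a placement exists for window position *p* iff the protospacer
starting *p*−1 bases 5' of the target C carries a matching PAM. `bescan`
enumerates every such placement on either strand, reports bystander
cytosines in the window, and flags *preferential* guides — placements where
the target is the **only** window cytosine, so clean editing is expected.

The package is aimed at researchers triaging SNVs for base-editing
experiments: it answers "which editors in my panel can hit this variant, with
which gRNA spacer, and how cleanly", and then "how well did the edit work"
from targeted amplicon sequencing (substitution frequency, indel frequency,
C→T product purity, editor-normalised efficiencies, one-tailed Wilcoxon
rank-sum comparisons).

## Worked example

Scan a free sequence with a custom NGG editor (spacer 20 nt, window 4–8):

```bash
$ bescan scan --seq TTTACAGTACGTTAAGCCTTAGGCATTCGATG \
    --pam NGG --spacer-length 20 --window-start 4 --window-end 8
position  strand  editor  protospacer_start  protospacer_end  spacer_seq            pam_seq  window_pos  bystanders  preferential
5         +       custom  1                  20               TTTACAGTACGTTAAGCCTT  AGG      5           .           true
```

Read: the C at position 5 (1-based, plus strand) can be edited by a guide
whose protospacer spans positions 1–20 with the AGG PAM immediately 3'; the
C sits at window position 5 and no other C falls in positions 4–8
(`bystanders = .`), so the guide is preferential. The `spacer_seq` column is
what you order as the gRNA spacer.

The bundled panel of 20 editor geometries (each entry cites the publication
its PAM/window/spacer values come from) is printed by:

```bash
$ bescan panel list
name    pam  pam_side     spacer  window  citation
BE3     NGG  three_prime  20      4-8     Komor et al. 2016 Nature 533:420
eBE-S3  NGG  three_prime  20      4-8     Wang et al. 2017 Cell Res 27:1289
...
```

Variant-centred search over a genome + ClinVar-style table (or VCF):

```bash
bescan search --genome genome.fa --variants variants.tsv --out-prefix out
```

writes `out.candidates.tsv` (one row per guide placement, with genomic
protospacer coordinates, spacer/PAM sequences, window position, bystanders,
preferential flag) and `out.summary.tsv` (per variant: targetable and
preferential editor sets, plus the union/intersection combination). The
filtering pipeline — SNV type → exact "pathogenic" significance → GRCh38 →
site deduplication — logs its per-step counts to stderr. `bescan quant` and
`bescan simulate` expose the amplicon metrics and the synthetic-fixture
generators from the shell.

As a library:

```python
from bescan import default_panel, scan_sequence
hits = scan_sequence("TTTACAGTACGTTAAGCCTTAGGCATTCGATG", default_panel())
```

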