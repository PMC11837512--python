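# bestop

Knockout-guide design for CRISPR cytosine base editors, by premature stop
codon introduction, plus Sanger-signal quantification of editing efficiency.

## The problem

A cytosine base editor (CBE; an nCas9(D10A)–cytidine deaminase fusion)
converts C·G base pairs to T·A inside a narrow window at the PAM-distal end
of the protospacer, without double-strand breaks or donor DNA. In bacteria
this is a practical route to template-free, multiplexable gene knockouts:
if a window cytosine sits in the right codon, the C→T edit converts a sense
codon into an in-frame premature stop. Exactly four sense codons can be
inactivated this way:

* on the coding strand, **CGA → TGA**, **CAG → TAG**, **CAA → TAA**
  (direct C→T at the first codon position);
* **TGG**, whose template-strand complement CCA carries two editable Cs —
  converting either or both gives **TGA**, **TAG** or **TAA**.

`bestop` scans a genome for all 20-nt + NGG protospacers on both strands
(PAM positions 0–2, spacer positions −20…−1), maps each window cytosine
through the annotated reading frame, and reports every (guide, gene) pair
whose allowed edits create a stop upstream of the native one. The
deamination window is the canonical −20…−16 by default, or −20…−13 to
include the positions where editing is observed at reduced efficiency.
Spacer uniqueness is called by exact-match occurrence counting (a spacer is
unique iff it occurs exactly once 5′ of an NGG, both strands counted).
Coverage statistics summarise, over the whole gene universe, how many genes
are deactivatable, how many guides and distinct editable codons each gene
has, and where the introduced stops fall within genes.

The four-codon rule set above is not hard-coded: `pre_stop_codons()` derives
it by brute force over all 64 codons × all edit subsets × both strands, and
the designer works directly on edited coding sequences, so multi-C edits and
codons split across CDS segments are handled by construction.

Editing outcomes measured by Sanger sequencing are quantified from
per-position base signals: for a target C, the C-to-T efficiency is
T/(A+T+C+G) and the C-to-G efficiency (glycosylase base editors) is
G/(A+T+C+G).

## Worked example

Generate a 10-gene synthetic genome with planted targets, design guides with
the extended window, and summarise coverage:

```sh
bestop fixture --n-genes 10 --seed 7 --out-prefix fix
bestop design --fasta fix.fasta --gff fix.gff3 --window extended --out-prefix fix
bestop stats --catalog fix.guides.tsv --gff fix.gff3 --out fix.summary.tsv
```

```
[bestop] 10 genes, 11 planted targets, 3 decoys
[bestop] loaded 1 contig(s), 4,118 bp
[bestop] loaded 10 gene(s), 10 validated
[bestop] scanned 515 protospacer sites; 11 stop-introducing guides; 11 unique spacers
[bestop] 7/10 genes editable (70.0%); 0 genes with >=4 guides
```

All 11 planted targets (and none of the 3 decoys) are recovered; the 7/10
editable genes reflect that plants were concentrated on seven genes. The
catalog starts:

```
gene_id  contig  strand  protospacer_start  protospacer_end  spacer                pam  codon_index  stop_codon  relative_position  unique
g001     c1      -       297                320              TACGCCCAGTTTACTTGCTG  TGG  13           TAG         0.142857           True
g003     c1      +       882                905              TCTCGAGGACCAGCTTTCAC  TGG  19           TGA         0.22619            True
```

Row one: a guide on the minus strand whose window C converts codon 13 of
`g001` (14% into the gene) into the amber stop TAG; its spacer is unique in
the genome. Coordinates are 0-based half-open; `protospacer_start/end` span
the 23-nt protospacer+PAM.

For a real bacterial genome, point `--fasta/--gff` at the assembly and its
CDS annotation (or load a GenBank flat file via
`bestop.genome_model.load_genbank`), then compare the window × edit-policy
grid. Efficiency quantification from an EditR-style signal table:

```sh
bestop efficiency --table signals.tsv --targets 5,7
```

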