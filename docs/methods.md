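# Methods

## Editing model

The designer models a cytosine base editor as a pure C·G→T·A substitution
process confined to the protospacer's deamination window. Each protospacer
is a 20-nt spacer followed by an NGG PAM; positions are numbered with the
PAM at 0–2 and the spacer at −20 (5′, PAM-distal) … −1 (PAM-proximal). Only
cytosines on the protospacer strand are editable. Read on a gene's coding
strand, an edit is C→T when the protospacer rides the coding strand and G→A
when it rides the template strand (the deaminated C pairs the coding-strand
G). Editing-efficiency differences between window positions are not
modelled; window membership is binary.

Two windows are provided:

* `canonical` = positions −20…−16, the ~5-bp window where deamination is
  efficient (default);
* `extended` = −20…−13, adding the flank where editing is observed at
  reduced efficiency (high at −15/−14, low at −13). These tiers are treated
  qualitatively; no per-position rate enters the computation.

A guide inactivates a gene when its allowed window edits convert a sense
codon into TAA/TAG/TGA strictly upstream of the gene's native (first
in-frame) stop. The stop at the last codon never counts. The four-codon
rule set (CGA/CAG/CAA on the coding strand, TGG via the template-strand
CCA) is derived, not assumed: `pre_stop_codons()` enumerates all 64 codons
× all non-empty C/G edit subsets × both strands, and `classify_site()`
applies edits to the actual coding sequence and re-scans for the first
stop, which also covers multi-codon windows and CDS intervals joined across
segments.

## Edit policies

Whether co-editing of multiple window Cs should be assumed is biologically
ambiguous, so both policies are explicit configuration:

* `any-subset` (default): a guide qualifies if there exists a non-empty
  subset of its in-CDS window edits creating a premature stop; the minimal
  such subset (searched smallest-first in deterministic order) is recorded,
  remaining window edits are reported as collateral.
* `all-window-cs`: every in-CDS window C is assumed co-edited and only that
  single outcome is tested. This matters when a co-edit destroys the
  stop-creating context.

Both windows × both policies form the 2×2 grid the genome-scale protocol
evaluates, because published genome-wide counts rarely state either
convention.

## Coordinates, gene universe, uniqueness

All internal coordinates are 0-based half-open on the forward strand;
GFF3's 1-based inclusive convention is converted only at the parsing
boundary, which confines off-by-one risk to one function. One gene model
per GFF3 CDS group (joined in translation order); non-coding features are
ignored. Genes whose CDS length is not a multiple of 3 or whose CDS
contains N stay in the gene universe (the denominator of coverage
fractions) but are excluded from design — a conservative choice that can
only lower the reported editable fraction. Contigs default to linear
topology; an option extends the PAM scan across the origin of circular
replicons (origin-spanning guides are a negligible minority, so this is off
by default).

Spacer uniqueness is exact-match multiplicity: a guide is unique iff its
20-nt spacer occurs exactly once immediately 5′ of an NGG genome-wide, both
strands counted. No mismatch-tolerant off-target search is attempted; exact
multiplicity is the minimal defensible definition and is independently
recountable. Non-unique guides are retained but flagged, and coverage
statistics count unique guides only by default.

Guides are catalogued per (protospacer, gene) pair: a guide overlapping two
genes yields two rows; the headline "unique gRNAs" count collapses to
distinct unique spacers. Catalog ordering is a stable sort by (contig,
start, strand, gene), and every export carries a provenance block (config
snapshot + genome MD5), making repeated runs byte-identical.

## Efficiency quantification

Input is a per-position A/C/G/T signal table (peak areas or frequencies;
EditR-style), not raw chromatograms — trace processing is upstream. For a
target C: ct = T/(A+T+C+G), cg = G/(A+T+C+G). The formulas are
scale-invariant, so normalised or raw peak signals give identical results.
No "edited/unedited" binarisation threshold is applied; callers can
threshold downstream. Rows with zero total signal or non-C references are
rejected rather than silently skipped.

## Synthetic genomes and the oracle

`make_genome` emulates a compact prokaryotic genome: single-interval CDSs
with ATG starts and random stop codons on both strands, separated by random
intergenic pads. Its key property is an exactly known guide set:

* random codons are drawn from the 57 sense codons that are neither stops
  nor pre-stop codons, so unplanted codons can never yield a premature stop
  under any edit subset;
* each planted target writes a pre-stop codon and constrains surrounding
  bases so exactly one NGG site places its editable C (for TGG: the CCA Cs)
  at the requested window position, while every alternative PAM geometry
  within the extended window of every planted base is destroyed by
  forbidden-base constraints. Plants are spaced ≥16 codons apart so
  constraint footprints cannot collide, at least 8 codons from the start
  and 9 from the stop so footprints stay inside the CDS.
* decoy variants (no PAM, C outside any window, non-pre-stop codon with a
  real site) and deliberate spacer duplications (for exercising the
  uniqueness flag) are available.

The generator self-checks by running the brute-force oracle on its own
output and comparing against the manifest.

The generator does not emulate: realistic GC content or codon usage,
multi-interval CDSs (supported by the designer, exercised by hand-built
cases in the tests), overlapping genes, or Ns. Passing the oracle-
equivalence study therefore demonstrates the correctness of the scanning,
frame-mapping and stop logic on clean annotations — not robustness to messy
real-world annotation, which the loader's validation flags handle
separately.

`brute_force_design` is the independent oracle: it enumerates every 23-mer
NGG occurrence by direct string scanning, literally applies each allowed
edit subset to a mutable copy of the genome, re-extracts and re-translates
every overlapping CDS, and reports (site, gene) pairs whose first stop
moves upstream. It shares no code with the scanner or classifier and is
deliberately quadratic; it is intended for genomes up to ~100 kb.

## Problem sizes and numerical choices

The validation study in `scripts/acceptance.py` uses ten seeded 20-gene
genomes of roughly 30 kb (100–200 codons per gene, 700–1,100 nt pads) for
the 2×2-grid oracle comparison — large enough to contain hundreds of
protospacer sites and dozens of planted targets per genome while keeping
the quadratic oracle comfortable — plus one denser 60-gene genome (up to
six plants per gene) for coverage statistics, so the ≥4-guides-per-gene
tail is populated. The per-test-suite study uses the same genome shape over
20 seeds. All pseudo-randomness is `random.Random(seed)`-driven and seeds
recorded in manifests, making every fixture bit-reproducible.

Relative stop positions are binned into 10 equal bins on [0, 1) by default
(bin width is a parameter; the positional distribution is over distinct
editable codons, not guides). `genes_with_at_least(k)` equals the histogram
tail sum exactly. No floating-point tolerance enters the designer itself —
all core computation is on integers and strings; efficiencies are plain
ratios of floats.

## Known limitations

* No activity or specificity scoring: guides are not ranked, and uniqueness
  is exact-match only.
* Editing is all-or-none within the window; positional efficiency tiers are
  not used quantitatively.
* Premature-stop creation is the only consequence modelled; missense or
  readthrough effects of collateral edits are reported but not interpreted.
* Genome-scale coverage claims depend on the annotation used for the gene
  universe (e.g. whether pseudogenes carry CDS features); the gene universe
  is whatever the provided GFF3/GenBank calls a CDS.
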