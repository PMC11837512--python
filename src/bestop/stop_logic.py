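"""Codon-level consequences of C.G -> T.A base editing.

A cytosine base editor deaminates Cs on the protospacer strand.  Read on the
coding strand of a gene this is either a direct C->T (protospacer on the
coding strand) or a G->A (protospacer on the template strand, where the
deaminated C pairs the coding-strand G).  A guide inactivates a gene when
some allowed subset of its window edits converts a sense codon into an
in-frame premature stop (TAA, TAG or TGA) upstream of the native stop.

The four-codon rule set used in the field (CGA->TGA, CAG->TAG, CAA->TAA on
the coding strand; TGG -> TGA/TAG/TAA via the template-strand CCA) is not
hard-coded: :func:`pre_stop_codons` derives it by exhaustive enumeration and
:func:`classify_site` works directly on the edited coding sequence.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .genome_model import (
    GeneModel,
    GenomeRecord,
    STOP_CODONS,
    coding_sequence,
    first_stop_index,
    genome_index,
)
from .guide_scan import EditWindow, ProtospacerSite, editable_cs

EDIT_STRANDS = ("coding", "template")
POLICIES = ("any-subset", "all-window-cs")


@dataclass(frozen=True)
class CodonEdit:
    """One codon's change under a set of same-strand deamination edits."""

    codon_index: int
    original_codon: str
    edited_codon: str
    edit_positions: frozenset[int]  # within-codon offsets 0..2
    edit_strand: str  # "coding" | "template"


@dataclass(frozen=True)
class StopGuide:
    """A protospacer classified as introducing a premature stop in one gene."""

    site: ProtospacerSite
    gene_id: str
    codon_edits: tuple[CodonEdit, ...]
    stop_codon: str
    stop_codon_index: int
    relative_position: float
    collateral_edits: tuple[CodonEdit, ...] = ()

    def __post_init__(self) -> None:
        if self.stop_codon not in STOP_CODONS:
            raise ValueError(f"{self.stop_codon!r} is not a stop codon")
        if not 0.0 <= self.relative_position < 1.0:
            raise ValueError("relative_position must lie in [0, 1)")

    @property
    def key(self) -> tuple[str, str, int, str]:
        """Identity of the (site, gene) pair: (contig, strand, start, gene)."""
        return (self.site.contig_id, self.site.strand, self.site.start, self.gene_id)


def apply_ct_edits(codon: str, offsets: Iterable[int], edit_strand: str) -> str:
    """Apply C->T (coding) or G->A (template) edits at within-codon offsets.

    Pure function; raises if a targeted base is not editable on that strand.
    """
    if edit_strand not in EDIT_STRANDS:
        raise ValueError(f"unknown edit strand {edit_strand!r}")
    src, dst = ("C", "T") if edit_strand == "coding" else ("G", "A")
    bases = list(codon)
    for off in offsets:
        if bases[off] != src:
            raise ValueError(
                f"codon {codon!r} has {bases[off]!r}, not {src!r}, at offset {off}"
            )
        bases[off] = dst
    return "".join(bases)


def pre_stop_codons() -> dict[str, set[tuple[str, frozenset[int], str]]]:
    """Every sense codon convertible to a stop by same-strand deamination.

    Brute force over all 64 codons, both edit strands, and every non-empty
    subset of editable offsets.  Returns codon -> {(edit_strand, offsets,
    resulting stop)}.
    """
    result: dict[str, set[tuple[str, frozenset[int], str]]] = {}
    for codon in map("".join, itertools.product("ACGT", repeat=3)):
        if codon in STOP_CODONS:
            continue
        for strand in EDIT_STRANDS:
            src = "C" if strand == "coding" else "G"
            editable = [i for i in range(3) if codon[i] == src]
            for r in range(1, len(editable) + 1):
                for offsets in itertools.combinations(editable, r):
                    edited = apply_ct_edits(codon, offsets, strand)
                    if edited in STOP_CODONS:
                        result.setdefault(codon, set()).add(
                            (strand, frozenset(offsets), edited)
                        )
    return result


def _codon_edits(
    cds: str,
    offsets: Sequence[int],
    edit_strand: str,
) -> tuple[CodonEdit, ...]:
    """Group coding-sequence offsets into per-codon CodonEdit records."""
    by_codon: dict[int, list[int]] = {}
    for o in offsets:
        by_codon.setdefault(o // 3, []).append(o % 3)
    edits = []
    for idx in sorted(by_codon):
        original = cds[3 * idx : 3 * idx + 3]
        within = frozenset(by_codon[idx])
        edits.append(
            CodonEdit(idx, original, apply_ct_edits(original, within, edit_strand),
                      within, edit_strand)
        )
    return tuple(edits)


def classify_site(
    site: ProtospacerSite,
    gene: GeneModel,
    genome: Sequence[GenomeRecord] | Mapping[str, GenomeRecord],
    window: EditWindow,
    policy: str = "any-subset",
) -> StopGuide | None:
    """Decide whether a protospacer's window edits create a premature stop.

    Window Cs are mapped through the gene's reading frame; Cs outside the CDS
    are ignored.  Under ``any-subset`` the guide qualifies if some non-empty
    subset of in-CDS window edits yields a stop strictly upstream of the
    native (first original) stop; the minimal such subset, searched in
    deterministic order, is recorded.  Under ``all-window-cs`` every in-CDS
    window C is assumed co-edited and that single outcome is tested.
    Window edits outside the chosen subset are reported as collateral.
    """
    if policy not in POLICIES:
        raise ValueError(f"unknown edit policy {policy!r}")
    if site.contig_id != gene.contig_id:
        raise ValueError("site and gene are on different contigs")
    if not gene.validated:
        return None
    contigs = genome if isinstance(genome, Mapping) else genome_index(genome)
    contig_len = len(contigs[gene.contig_id])
    edit_strand = "coding" if site.strand == gene.strand else "template"

    cds_offsets: list[int] = []
    for _pos, coord in editable_cs(site, window):
        offset = gene.coding_offset(coord % contig_len)
        if offset is not None:
            cds_offsets.append(offset)
    if not cds_offsets:
        return None
    cds_offsets.sort()

    cds = coding_sequence(gene, contigs)
    native_stop = first_stop_index(cds)

    def outcome(subset: Sequence[int]) -> tuple[int, str] | None:
        bases = list(cds)
        for o in subset:
            # coding-strand base is C when the protospacer rides the coding
            # strand, G when it rides the template strand
            bases[o] = "T" if edit_strand == "coding" else "A"
        edited = "".join(bases)
        idx = first_stop_index(edited)
        if idx < native_stop:
            return idx, edited[3 * idx : 3 * idx + 3]
        return None

    chosen: Sequence[int] | None = None
    hit: tuple[int, str] | None = None
    if policy == "all-window-cs":
        hit = outcome(cds_offsets)
        if hit is not None:
            chosen = cds_offsets
    else:
        for r in range(1, len(cds_offsets) + 1):
            for subset in itertools.combinations(cds_offsets, r):
                hit = outcome(subset)
                if hit is not None:
                    chosen = list(subset)
                    break
            if chosen is not None:
                break
    if chosen is None or hit is None:
        return None

    stop_index, stop_codon = hit
    stop_edit_offsets = [o for o in chosen if o // 3 == stop_index]
    other_offsets = [o for o in cds_offsets if o // 3 != stop_index]
    return StopGuide(
        site=site,
        gene_id=gene.gene_id,
        codon_edits=_codon_edits(cds, stop_edit_offsets, edit_strand),
        stop_codon=stop_codon,
        stop_codon_index=stop_index,
        relative_position=stop_index / gene.codon_count,
        collateral_edits=_codon_edits(cds, other_offsets, edit_strand),
    )
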