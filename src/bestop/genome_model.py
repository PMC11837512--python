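"""Genome sequences and strand-aware CDS coordinate models.

All internal coordinates are 0-based, half-open, on the forward (plus)
strand of a contig.  Conversion from the 1-based inclusive convention of
GFF3 happens only at the parsing boundary.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, Union

import gffutils
from Bio import SeqIO

ALPHABET = frozenset("ACGTN")
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

Source = Union[str, os.PathLike, io.IOBase]


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case DNA string over {A,C,G,T,N}."""
    return seq.translate(_COMPLEMENT)[::-1]


class GenomeModelError(ValueError):
    """Raised on malformed genome or annotation input."""


@dataclass(frozen=True)
class GenomeRecord:
    """One contig: an upper-case DNA sequence with a label and topology."""

    contig_id: str
    sequence: str
    topology: str = "linear"  # "linear" | "circular"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise GenomeModelError(f"contig {self.contig_id!r}: empty sequence")
        if self.topology not in ("linear", "circular"):
            raise GenomeModelError(f"unknown topology {self.topology!r}")
        bad = set(self.sequence) - ALPHABET
        if bad:
            raise GenomeModelError(
                f"contig {self.contig_id!r}: illegal characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneModel:
    """A protein-coding gene as an ordered set of CDS intervals on one contig.

    ``cds_intervals`` are 0-based half-open forward-strand intervals sorted in
    genomic order and non-overlapping.  ``validated`` is False when the total
    CDS length is not a multiple of three or the CDS contains N; such genes
    stay in the gene universe but are excluded from guide design.
    """

    gene_id: str
    contig_id: str
    strand: str  # "+" | "-"
    cds_intervals: tuple[tuple[int, int], ...]
    validated: bool = True

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise GenomeModelError(f"gene {self.gene_id!r}: strand must be + or -")
        prev_end = None
        for start, end in self.cds_intervals:
            if not (0 <= start < end):
                raise GenomeModelError(
                    f"gene {self.gene_id!r}: bad interval [{start}, {end})"
                )
            if prev_end is not None and start < prev_end:
                raise GenomeModelError(
                    f"gene {self.gene_id!r}: intervals overlap or are unsorted"
                )
            prev_end = end

    @property
    def cds_length(self) -> int:
        return sum(end - start for start, end in self.cds_intervals)

    @property
    def codon_count(self) -> int:
        return self.cds_length // 3

    @property
    def span(self) -> tuple[int, int]:
        return self.cds_intervals[0][0], self.cds_intervals[-1][1]

    def contains(self, coord: int) -> bool:
        return any(start <= coord < end for start, end in self.cds_intervals)

    def coding_offset(self, coord: int) -> int | None:
        """Map a forward-strand genome coordinate to a 0-based position in the
        coding sequence (translation order), or None if outside the CDS."""
        cum = 0
        offset = None
        for start, end in self.cds_intervals:
            if start <= coord < end:
                offset = cum + (coord - start)
            cum += end - start
        if offset is None:
            return None
        if self.strand == "-":
            return cum - 1 - offset
        return offset


def _as_text(source: Source) -> io.StringIO:
    """Accept a path, an open handle, or raw text and return a text handle."""
    if isinstance(source, io.IOBase):
        return io.StringIO(source.read())
    if isinstance(source, os.PathLike) or (
        isinstance(source, str) and "\n" not in source and os.path.exists(source)
    ):
        with open(source) as fh:
            return io.StringIO(fh.read())
    if isinstance(source, str):
        return io.StringIO(source)
    raise TypeError(f"cannot read from {type(source).__name__}")


def load_genome(
    fasta_source: Source,
    *,
    strict: bool = True,
    topology: str = "linear",
) -> list[GenomeRecord]:
    """Load a (multi-)FASTA into :class:`GenomeRecord` objects.

    Sequences are upper-cased and U is mapped to T.  In strict mode any
    character outside {A,C,G,T,N} is an error; otherwise it is mapped to N.
    Record order is preserved; duplicate contig ids are always an error.
    """
    handle = _as_text(fasta_source)
    records: list[GenomeRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(handle, "fasta"):
        if rec.id in seen:
            raise GenomeModelError(f"duplicate contig id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper().replace("U", "T")
        bad = set(seq) - ALPHABET
        if bad:
            if strict:
                raise GenomeModelError(
                    f"contig {rec.id!r}: illegal characters {sorted(bad)}"
                )
            seq = "".join(c if c in ALPHABET else "N" for c in seq)
        records.append(GenomeRecord(rec.id, seq, topology))
    if not records:
        raise GenomeModelError("no FASTA records found")
    return records


def genome_index(genome: Iterable[GenomeRecord]) -> dict[str, GenomeRecord]:
    return {rec.contig_id: rec for rec in genome}


def _gene_key(feature: gffutils.Feature) -> str:
    parents = feature.attributes.get("Parent")
    if parents:
        return parents[0]
    ids = feature.attributes.get("ID")
    if ids:
        return ids[0]
    raise GenomeModelError(
        f"CDS at {feature.seqid}:{feature.start}-{feature.end} lacks ID/Parent"
    )


def load_annotation(
    gff_source: Source,
    genome: Sequence[GenomeRecord] | Mapping[str, GenomeRecord],
) -> list[GeneModel]:
    """Load GFF3 CDS features into :class:`GeneModel` objects.

    CDS segments sharing a Parent (or ID) are joined into one gene; 1-based
    inclusive GFF3 coordinates become 0-based half-open.  Genes whose CDS
    length is not a multiple of 3, or whose CDS contains N, are retained but
    flagged ``validated=False``.  Non-CDS features are ignored.
    """
    contigs = genome if isinstance(genome, Mapping) else genome_index(genome)
    text = _as_text(gff_source).getvalue()
    if not any(line.strip() and not line.startswith("#") for line in text.splitlines()):
        return []
    db = gffutils.create_db(
        text,
        dbfn=":memory:",
        from_string=True,
        merge_strategy="create_unique",
        keep_order=True,
    )
    grouped: dict[str, list[gffutils.Feature]] = {}
    order: list[str] = []
    for feat in db.features_of_type("CDS", order_by=("seqid", "start")):
        key = _gene_key(feat)
        if key not in grouped:
            grouped[key] = []
            order.append(key)
        grouped[key].append(feat)

    genes: list[GeneModel] = []
    for gene_id in order:
        feats = grouped[gene_id]
        contig_ids = {f.seqid for f in feats}
        if len(contig_ids) > 1:
            raise GenomeModelError(f"gene {gene_id!r}: CDS on multiple contigs")
        contig_id = contig_ids.pop()
        if contig_id not in contigs:
            raise GenomeModelError(f"gene {gene_id!r}: unknown contig {contig_id!r}")
        strands = {f.strand for f in feats}
        if len(strands) > 1:
            raise GenomeModelError(f"gene {gene_id!r}: CDS on both strands")
        strand = strands.pop()
        if strand not in ("+", "-"):
            raise GenomeModelError(f"gene {gene_id!r}: missing strand")
        contig_len = len(contigs[contig_id])
        intervals = []
        for f in sorted(feats, key=lambda f: f.start):
            start, end = f.start - 1, f.end  # GFF3 1-based inclusive -> half-open
            if start < 0 or end > contig_len:
                raise GenomeModelError(
                    f"gene {gene_id!r}: interval [{start}, {end}) outside contig"
                )
            intervals.append((start, end))
        gene = GeneModel(gene_id, contig_id, strand, tuple(intervals))
        cds = coding_sequence(gene, contigs, validated_only=False)
        validated = gene.cds_length % 3 == 0 and "N" not in cds
        if not validated:
            gene = GeneModel(gene_id, contig_id, strand, tuple(intervals), False)
        genes.append(gene)
    return genes


def load_genbank(
    gb_source: Source, *, topology: str | None = None
) -> tuple[list[GenomeRecord], list[GeneModel]]:
    """Read a GenBank flat file into genome records plus gene models.

    Every CDS feature becomes one GeneModel (joined locations become
    multi-interval CDS); the gene id is the locus_tag, falling back to
    gene/protein_id or a positional label.  Topology is taken from the
    GenBank header unless overridden.
    """
    records: list[GenomeRecord] = []
    genes: list[GeneModel] = []
    seen_ids: set[str] = set()
    for rec in SeqIO.parse(_as_text(gb_source), "genbank"):
        rec_topology = topology or (
            "circular"
            if rec.annotations.get("topology") == "circular"
            else "linear"
        )
        seq = str(rec.seq).upper().replace("U", "T")
        seq = "".join(c if c in ALPHABET else "N" for c in seq)
        record = GenomeRecord(rec.id, seq, rec_topology)
        records.append(record)
        for n, feat in enumerate(f for f in rec.features if f.type == "CDS"):
            quals = feat.qualifiers
            gene_id = (
                quals.get("locus_tag", quals.get("gene", quals.get("protein_id", [])))
                or [f"{rec.id}.cds{n}"]
            )[0]
            if gene_id in seen_ids:  # e.g. split CDS emitted twice
                gene_id = f"{gene_id}.{n}"
            seen_ids.add(gene_id)
            strand = "-" if feat.location.strand == -1 else "+"
            intervals = tuple(
                sorted((int(part.start), int(part.end)) for part in feat.location.parts)
            )
            gene = GeneModel(gene_id, rec.id, strand, intervals)
            cds = coding_sequence(gene, [record], validated_only=False)
            if gene.cds_length % 3 != 0 or "N" in cds:
                gene = GeneModel(gene_id, rec.id, strand, intervals, False)
            genes.append(gene)
    if not records:
        raise GenomeModelError("no GenBank records found")
    return records, genes


def coding_sequence(
    gene: GeneModel,
    genome: Sequence[GenomeRecord] | Mapping[str, GenomeRecord],
    *,
    validated_only: bool = True,
) -> str:
    """Strand-corrected, concatenated CDS of a gene (translation order)."""
    contigs = genome if isinstance(genome, Mapping) else genome_index(genome)
    if validated_only and not gene.validated:
        raise GenomeModelError(f"gene {gene.gene_id!r} is not validated")
    seq = contigs[gene.contig_id].sequence
    joined = "".join(seq[start:end] for start, end in gene.cds_intervals)
    return revcomp(joined) if gene.strand == "-" else joined


def first_stop_index(cds: str) -> int:
    """Index of the first in-frame stop codon, or the codon count if none."""
    n = len(cds) // 3
    for i in range(n):
        if cds[3 * i : 3 * i + 3] in STOP_CODONS:
            return i
    return n


def write_fasta(records: Iterable[GenomeRecord], width: int = 70) -> str:
    lines = []
    for rec in records:
        lines.append(f">{rec.contig_id}")
        for i in range(0, len(rec.sequence), width):
            lines.append(rec.sequence[i : i + width])
    return "\n".join(lines) + "\n"


def write_gff3(genes: Iterable[GeneModel]) -> str:
    lines = ["##gff-version 3"]
    for gene in genes:
        start, end = gene.span
        lines.append(
            "\t".join(
                [
                    gene.contig_id,
                    "bestop",
                    "gene",
                    str(start + 1),
                    str(end),
                    ".",
                    gene.strand,
                    ".",
                    f"ID={gene.gene_id}",
                ]
            )
        )
        for i, (s, e) in enumerate(gene.cds_intervals):
            lines.append(
                "\t".join(
                    [
                        gene.contig_id,
                        "bestop",
                        "CDS",
                        str(s + 1),
                        str(e),
                        ".",
                        gene.strand,
                        "0" if len(gene.cds_intervals) == 1 else ".",
                        f"ID={gene.gene_id}.cds{i};Parent={gene.gene_id}",
                    ]
                )
            )
    return "\n".join(lines) + "\n"
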