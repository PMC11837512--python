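"""Genome-wide knockout-guide design: scan, classify, uniqueness, export.

The designer enumerates every NGG protospacer on both strands, classifies
each against every protein-coding gene its editing window touches, flags
spacer uniqueness by exact-match occurrence counting, and emits a
deterministic, provenance-stamped catalog.
"""

from __future__ import annotations

import hashlib
import json
from collections import Counter
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .genome_model import GeneModel, GenomeRecord, genome_index
from .guide_scan import EditWindow, ProtospacerSite, editable_cs, find_pam_sites
from .stop_logic import POLICIES, StopGuide, classify_site


@dataclass(frozen=True)
class DesignConfig:
    """Designer settings.

    window_mode: 'canonical' (-20..-16) or 'extended' (-20..-13).
    policy: 'any-subset' (a guide qualifies if some subset of window edits
        creates a stop) or 'all-window-cs' (every window C is co-edited).
    uniqueness: 'exact-spacer-ngg' — a guide is unique iff its 20-nt spacer
        immediately 5' of an NGG occurs exactly once genome-wide (both
        strands).
    max_relative_position: optional cap on the stop's relative position in
        the gene (e.g. 0.95); None disables the filter.
    circular: scan protospacers across the contig origin.
    """

    window_mode: str = "canonical"
    policy: str = "any-subset"
    uniqueness: str = "exact-spacer-ngg"
    max_relative_position: float | None = None
    circular: bool = False

    def __post_init__(self) -> None:
        EditWindow.from_mode(self.window_mode)  # validates
        if self.policy not in POLICIES:
            raise ValueError(f"unknown edit policy {self.policy!r}")
        if self.uniqueness != "exact-spacer-ngg":
            raise ValueError(f"unknown uniqueness rule {self.uniqueness!r}")


TSV_COLUMNS = [
    "gene_id",
    "contig",
    "strand",
    "protospacer_start",
    "protospacer_end",
    "spacer",
    "pam",
    "codon_index",
    "original_codon",
    "edited_codon",
    "stop_codon",
    "relative_position",
    "unique",
]


@dataclass
class GuideCatalog:
    """The designed guide set plus uniqueness flags and provenance."""

    guides: list[StopGuide]
    unique_flags: list[bool]
    provenance: dict

    def __post_init__(self) -> None:
        if len(self.guides) != len(self.unique_flags):
            raise ValueError("one uniqueness flag per guide required")
        keys = [g.key for g in self.guides]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (contig, strand, start, gene) entries")

    def __len__(self) -> int:
        return len(self.guides)

    @property
    def n_unique_spacers(self) -> int:
        """Distinct spacer sequences among guides flagged unique — the
        'unique gRNAs usable for gene inactivation' headline count."""
        return len(
            {g.site.spacer for g, u in zip(self.guides, self.unique_flags) if u}
        )

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for guide, unique in zip(self.guides, self.unique_flags):
            stop_edits = guide.codon_edits
            original = "+".join(e.original_codon for e in stop_edits)
            edited = "+".join(e.edited_codon for e in stop_edits)
            rows.append(
                {
                    "gene_id": guide.gene_id,
                    "contig": guide.site.contig_id,
                    "strand": guide.site.strand,
                    "protospacer_start": guide.site.start,
                    "protospacer_end": guide.site.end,
                    "spacer": guide.site.spacer,
                    "pam": guide.site.pam,
                    "codon_index": guide.stop_codon_index,
                    "original_codon": original,
                    "edited_codon": edited,
                    "stop_codon": guide.stop_codon,
                    "relative_position": round(guide.relative_position, 6),
                    "unique": unique,
                }
            )
        return pd.DataFrame(rows, columns=TSV_COLUMNS)

    def to_tsv(self) -> str:
        return self.to_dataframe().to_csv(sep="\t", index=False)

    def to_bed(self) -> str:
        """BED6 of protospacer+PAM spans (0-based half-open)."""
        lines = []
        for guide, unique in zip(self.guides, self.unique_flags):
            site = guide.site
            name = f"{guide.gene_id}|{guide.stop_codon}|{'U' if unique else 'R'}"
            lines.append(
                "\t".join(
                    [
                        site.contig_id,
                        str(site.start),
                        str(site.end),
                        name,
                        "0",
                        site.strand,
                    ]
                )
            )
        return "\n".join(lines) + ("\n" if lines else "")

    def provenance_json(self) -> str:
        return json.dumps(self.provenance, indent=2, sort_keys=True) + "\n"


def genome_checksum(genome: Sequence[GenomeRecord]) -> str:
    h = hashlib.md5()
    for rec in genome:
        h.update(rec.contig_id.encode())
        h.update(b"\0")
        h.update(rec.sequence.encode())
        h.update(b"\0")
    return h.hexdigest()


def _gene_trees(genes: Sequence[GeneModel]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for i, gene in enumerate(genes):
        tree = trees.setdefault(gene.contig_id, IntervalTree())
        for start, end in gene.cds_intervals:
            tree[start:end] = i
    return trees


def _spacer_counts(genome: Sequence[GenomeRecord], circular: bool) -> Counter:
    counts: Counter = Counter()
    for record in genome:
        for site in find_pam_sites(record, circular=circular):
            counts[site.spacer] += 1
    return counts


def design(
    genome: Sequence[GenomeRecord],
    genes: Sequence[GeneModel],
    config: DesignConfig = DesignConfig(),
) -> GuideCatalog:
    """Run the full design: every (protospacer, gene) pair whose window edits
    introduce a premature stop, sorted deterministically, with uniqueness
    flags and a provenance block."""
    contigs = genome_index(genome)
    window = EditWindow.from_mode(config.window_mode)
    trees = _gene_trees(genes)

    guides: list[StopGuide] = []
    seen: set[tuple] = set()
    n_sites = 0
    for record in genome:
        tree = trees.get(record.contig_id)
        if tree is None:
            continue
        contig_len = len(record)
        for site in find_pam_sites(record, circular=config.circular):
            n_sites += 1
            gene_idx: set[int] = set()
            for _pos, coord in editable_cs(site, window):
                for iv in tree[coord % contig_len]:
                    gene_idx.add(iv.data)
            for i in sorted(gene_idx):
                guide = classify_site(site, genes[i], contigs, window, config.policy)
                if guide is None:
                    continue
                if (
                    config.max_relative_position is not None
                    and guide.relative_position > config.max_relative_position
                ):
                    continue
                if guide.key in seen:
                    continue
                seen.add(guide.key)
                guides.append(guide)

    guides.sort(key=lambda g: (g.site.contig_id, g.site.start, g.site.strand, g.gene_id))
    counts = _spacer_counts(genome, config.circular)
    flags = [counts[g.site.spacer] == 1 for g in guides]
    provenance = {
        "tool": "bestop",
        "config": asdict(config),
        "genome_md5": genome_checksum(genome),
        "n_contigs": len(genome),
        "n_genes": len(genes),
        "n_protospacer_sites": n_sites,
        "n_guides": len(guides),
    }
    return GuideCatalog(guides, flags, provenance)


def spacer_uniqueness(
    catalog: GuideCatalog, genome: Sequence[GenomeRecord]
) -> GuideCatalog:
    """Recompute uniqueness flags against a genome: a spacer is unique iff
    it occurs exactly once immediately 5' of an NGG, counting both strands."""
    circular = bool(catalog.provenance.get("config", {}).get("circular", False))
    counts = _spacer_counts(genome, circular)
    flags = [counts[g.site.spacer] == 1 for g in catalog.guides]
    return GuideCatalog(catalog.guides, flags, catalog.provenance)
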