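"""Genome-wide coverage summaries of a knockout-guide catalog.

Answers the design-coverage questions: how many genes can be inactivated at
all, how many guides and how many distinct editable codons each gene has,
and where along the coding region the introduced stops fall.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .designer import GuideCatalog
from .genome_model import GeneModel

HISTOGRAM_BINS = ("0", "1", "2", "3", ">=4")


def _guide_frame(catalog: GuideCatalog | pd.DataFrame) -> pd.DataFrame:
    if isinstance(catalog, pd.DataFrame):
        required = {"gene_id", "codon_index", "relative_position", "unique"}
        missing = required - set(catalog.columns)
        if missing:
            raise ValueError(f"catalog frame missing columns {sorted(missing)}")
        return catalog
    return catalog.to_dataframe()


def _binned(counts: Counter, total_genes: int) -> dict[str, int]:
    """Fold per-gene counts into 0/1/2/3/>=4 bins; mass sums to total genes."""
    binned = {b: 0 for b in HISTOGRAM_BINS}
    nonzero = 0
    for _gene, k in counts.items():
        nonzero += 1
        binned[str(k) if k < 4 else ">=4"] += 1
    binned["0"] = total_genes - nonzero
    return binned


@dataclass(frozen=True)
class CoverageSummary:
    total_genes: int
    editable_genes: int
    editable_fraction: float
    guides_per_gene: dict[str, int]  # full distribution, gene_id -> count
    guides_per_gene_hist: dict[str, int]
    editable_codons_per_gene: dict[str, int]
    editable_codons_per_gene_hist: dict[str, int]
    relative_position_bin_edges: tuple[float, ...]
    relative_position_counts: tuple[int, ...]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("total_genes", self.total_genes),
            ("editable_genes", self.editable_genes),
            ("editable_fraction", round(self.editable_fraction, 6)),
        ]
        for b in HISTOGRAM_BINS:
            rows.append((f"genes_with_{b}_guides", self.guides_per_gene_hist[b]))
        for b in HISTOGRAM_BINS:
            rows.append(
                (f"genes_with_{b}_editable_codons", self.editable_codons_per_gene_hist[b])
            )
        edges = self.relative_position_bin_edges
        for i, count in enumerate(self.relative_position_counts):
            rows.append(
                (f"stops_in_[{edges[i]:.2f},{edges[i + 1]:.2f})", count)
            )
        return pd.DataFrame(rows, columns=["statistic", "value"])

    def to_tsv(self) -> str:
        return self.to_frame().to_csv(sep="\t", index=False)


def summarize(
    catalog: GuideCatalog | pd.DataFrame,
    genes: Sequence[GeneModel] | Sequence[str],
    *,
    unique_only: bool = True,
    position_bins: int = 10,
) -> CoverageSummary:
    """Coverage summary over the full gene universe.

    A gene is editable iff at least one (by default unique) guide targets it.
    ``editable_codons_per_gene`` counts distinct (gene, codon index) pairs.
    The relative-position histogram bins stop positions over [0, 1).
    """
    gene_ids = [g.gene_id if isinstance(g, GeneModel) else str(g) for g in genes]
    if len(set(gene_ids)) != len(gene_ids):
        raise ValueError("duplicate gene ids in gene universe")
    frame = _guide_frame(catalog)
    if unique_only:
        frame = frame[frame["unique"].astype(bool)]
    unknown = set(frame["gene_id"]) - set(gene_ids)
    if unknown:
        raise ValueError(f"catalog references genes outside the universe: {sorted(unknown)[:5]}")

    total = len(gene_ids)
    guide_counts = Counter(frame["gene_id"])
    codon_counts = Counter(
        {g: n for g, n in frame.groupby("gene_id")["codon_index"].nunique().items()}
    )
    editable = len(guide_counts)
    # positional distribution is over distinct editable codons, not guides
    codons = frame.drop_duplicates(subset=["gene_id", "codon_index"])
    positions = codons["relative_position"].to_numpy(dtype=float)
    counts, edges = np.histogram(positions, bins=position_bins, range=(0.0, 1.0))
    per_gene = {gid: int(guide_counts.get(gid, 0)) for gid in gene_ids}
    return CoverageSummary(
        total_genes=total,
        editable_genes=editable,
        editable_fraction=editable / total if total else 0.0,
        guides_per_gene=per_gene,
        guides_per_gene_hist=_binned(guide_counts, total),
        editable_codons_per_gene=
            {gid: int(codon_counts.get(gid, 0)) for gid in gene_ids},
        editable_codons_per_gene_hist=_binned(codon_counts, total),
        relative_position_bin_edges=tuple(float(e) for e in edges),
        relative_position_counts=tuple(int(c) for c in counts),
    )


def genes_with_at_least(
    catalog: GuideCatalog | pd.DataFrame,
    genes: Sequence[GeneModel] | Sequence[str],
    k: int,
    *,
    unique_only: bool = True,
) -> int:
    """Number of genes with at least ``k`` (by default unique) guides."""
    if k < 0:
        raise ValueError("k must be non-negative")
    if k == 0:
        return len(genes)
    frame = _guide_frame(catalog)
    if unique_only:
        frame = frame[frame["unique"].astype(bool)]
    counts = Counter(frame["gene_id"])
    return sum(1 for n in counts.values() if n >= k)


def plot_summary(summary: CoverageSummary, out_prefix: str) -> list[str]:
    """Write histogram figures (guides/gene, codons/gene, stop positions)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = []
    for name, hist in [
        ("guides_per_gene", summary.guides_per_gene_hist),
        ("editable_codons_per_gene", summary.editable_codons_per_gene_hist),
    ]:
        fig, ax = plt.subplots(figsize=(4, 3))
        ax.bar(list(hist), list(hist.values()), color="#4477aa")
        ax.set_xlabel(name.replace("_", " "))
        ax.set_ylabel("genes")
        fig.tight_layout()
        path = f"{out_prefix}.{name}.png"
        fig.savefig(path, dpi=150)
        plt.close(fig)
        written.append(path)

    fig, ax = plt.subplots(figsize=(4, 3))
    edges = summary.relative_position_bin_edges
    centers = [(edges[i] + edges[i + 1]) / 2 for i in range(len(edges) - 1)]
    width = edges[1] - edges[0]
    ax.bar(centers, summary.relative_position_counts, width=width * 0.9,
           color="#cc6677")
    ax.set_xlabel("relative stop position in gene")
    ax.set_ylabel("editable codons")
    fig.tight_layout()
    path = f"{out_prefix}.relative_positions.png"
    fig.savefig(path, dpi=150)
    plt.close(fig)
    written.append(path)
    return written
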