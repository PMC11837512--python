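"""Synthetic annotated genomes with planted, fully known base-editing targets.

The generator emits a small multi-gene prokaryotic-style genome (FASTA +
GFF3) whose guide catalog is known exactly:

* random CDS codons are drawn from the 57 sense codons that are neither
  stops nor pre-stop codons (CGA/CAG/CAA/TGG), so an unplanted codon can
  never yield a premature stop under any deamination edit;
* each planted target writes a pre-stop codon into the CDS and constrains
  the surrounding bases so that exactly one NGG site places the editable
  C (or the template-strand Cs of TGG's CCA) at the requested window
  position, while every alternative PAM geometry within the extended
  window of every planted base is actively destroyed;
* decoy variants (PAM absent, C outside any window, codon not pre-stop)
  and deliberate spacer duplications are available.

:func:`brute_force_design` is an independent oracle that shares no code
with the scanner/classifier: it enumerates 23-mers by hand, literally
applies every allowed edit subset to the genome string, re-extracts and
re-translates each CDS, and reports (site, gene) pairs that gain a stop
upstream of the native one.
"""

from __future__ import annotations

import itertools
import json
import random
from dataclasses import dataclass, field, asdict
from typing import Sequence

from .genome_model import (
    GeneModel,
    GenomeRecord,
    write_fasta,
    write_gff3,
)

PRE_STOP_CODONS = ("CGA", "CAG", "CAA", "TGG")
_STOPS = ("TAA", "TAG", "TGA")
_FORBIDDEN_RANDOM = frozenset(_STOPS) | frozenset(PRE_STOP_CODONS)
_SENSE_POOL = tuple(
    c
    for c in map("".join, itertools.product("ACGT", repeat=3))
    if c not in _FORBIDDEN_RANDOM
)

DECOY_KINDS = ("no_pam", "outside_window", "non_prestop")

# minimum codon-index spacing between plants: constraint footprints span
# at most ~23 nt either side of a planted codon
_MIN_PLANT_SPACING = 16
_MIN_PLANT_INDEX = 8
_END_MARGIN = 9  # keep constraints clear of the native stop codon


class FixtureError(ValueError):
    """Raised for infeasible plant specifications or generator self-check
    failures."""


@dataclass(frozen=True)
class Plant:
    """Request to plant one targetable (or decoy) codon in a gene.

    ``window_position`` is the protospacer position of the editable C for
    coding-strand codons (CGA/CAG/CAA; -20..-13) or of the PAM-proximal
    template-strand C for TGG (-19..-13; the second C then sits one position
    PAM-distal).  ``gene`` picks a gene index; None lets the generator
    assign one.  ``decoy`` in DECOY_KINDS plants a near-miss instead.
    """

    codon: str
    window_position: int | None = None
    gene: int | None = None
    decoy: str | None = None

    def __post_init__(self) -> None:
        if self.decoy is not None and self.decoy not in DECOY_KINDS:
            raise FixtureError(f"unknown decoy kind {self.decoy!r}")
        if self.decoy == "non_prestop":
            if self.codon in _FORBIDDEN_RANDOM:
                raise FixtureError("non_prestop decoy needs a non-pre-stop codon")
        elif self.codon not in PRE_STOP_CODONS:
            raise FixtureError(f"{self.codon!r} is not a pre-stop codon")
        if self.decoy in (None, "non_prestop"):
            lo = -19 if self.codon == "TGG" else -20
            if self.window_position is None or not lo <= self.window_position <= -13:
                raise FixtureError(
                    f"window position {self.window_position!r} infeasible for "
                    f"{self.codon} (allowed {lo}..-13)"
                )


@dataclass(frozen=True)
class PlantedSite:
    """Manifest record of one planted target, with its genome geometry."""

    gene_id: str
    contig_id: str
    gene_strand: str
    codon: str
    codon_index: int
    editable_positions: tuple[int, ...]  # window positions of editable Cs
    stop_codons: tuple[str, ...]
    site_strand: str  # protospacer strand in genome coordinates
    site_start: int  # plus-strand start of the 23-nt span; -1 for no_pam decoys
    spacer: str
    pam: str
    decoy: str | None = None


@dataclass(frozen=True)
class ManifestGene:
    gene_id: str
    contig_id: str
    strand: str
    start: int
    end: int
    codon_count: int
    cds: str


@dataclass(frozen=True)
class FixtureManifest:
    seed: int
    contig_lengths: dict[str, int]
    genes: tuple[ManifestGene, ...]
    planted: tuple[PlantedSite, ...]
    duplicated_spacers: tuple[str, ...] = ()

    def expected_guides(self, window_positions: Sequence[int]) -> set[tuple]:
        """(contig, strand, start, gene_id) keys of planted non-decoy sites
        whose editable C falls inside the given window."""
        window = set(window_positions)
        return {
            (p.contig_id, p.site_strand, p.site_start, p.gene_id)
            for p in self.planted
            if p.decoy is None and window.intersection(p.editable_positions)
        }

    def to_json(self) -> str:
        payload = asdict(self)
        return json.dumps(payload, indent=2, sort_keys=True) + "\n"


class _Constraints:
    """Exact-base and forbidden-base constraints over CDS-local positions."""

    def __init__(self) -> None:
        self.eq: dict[int, str] = {}
        self.ne: dict[int, set[str]] = {}

    def require(self, pos: int, base: str) -> None:
        if self.eq.get(pos, base) != base or base in self.ne.get(pos, ()):
            raise FixtureError(f"conflicting constraints at CDS position {pos}")
        self.eq[pos] = base

    def forbid(self, pos: int, base: str) -> None:
        if self.eq.get(pos) == base:
            raise FixtureError(f"conflicting constraints at CDS position {pos}")
        self.ne.setdefault(pos, set()).add(base)

    def forbid_pair(self, pos1: int, pos2: int, base: str) -> None:
        """Ensure positions pos1, pos2 are not both ``base``."""
        if self.eq.get(pos1) == base and self.eq.get(pos2) == base:
            raise FixtureError(
                f"cannot destroy {base}{base} pair at {pos1},{pos2}"
            )
        if self.eq.get(pos1) == base:
            self.forbid(pos2, base)
        else:
            self.forbid(pos1, base)

    def choices(self, pos: int) -> tuple[str, ...]:
        if pos in self.eq:
            return (self.eq[pos],)
        banned = self.ne.get(pos, set())
        return tuple(b for b in "ACGT" if b not in banned)


def _constrain_coding_plant(
    cons: _Constraints, codon: str, k: int, window_position: int | None,
    *, pam: bool
) -> None:
    """Codon with its editable C at offset 0 targeted by a same-strand site."""
    c = 3 * k
    for j, base in enumerate(codon):
        cons.require(c + j, base)
    i = None
    if window_position is not None:
        i = window_position + 20
        if pam:
            cons.require(c + 21 - i, "G")
            cons.require(c + 22 - i, "G")
    for j in range(8):  # extended-window geometries -20..-13
        if pam and j == i:
            continue
        cons.forbid_pair(c + 21 - j, c + 22 - j, "G")


def _constrain_tgg_plant(
    cons: _Constraints, k: int, window_position: int | None, *, pam: bool
) -> None:
    """TGG codon targeted through the template strand (CCA): the editable Cs
    are the coding-strand Gs at offsets 1 and 2."""
    c = 3 * k
    for j, base in enumerate("TGG"):
        cons.require(c + j, base)
    g1 = c + 1
    t = None
    if window_position is not None:
        t = g1 + window_position - 2
        if pam:
            cons.require(t, "C")
            cons.require(t + 1, "C")
    for g in (g1, g1 + 1):
        for p in range(-20, -12):
            t2 = g + p - 2
            if pam and t2 == t:
                continue
            cons.forbid_pair(t2, t2 + 1, "C")


@dataclass(frozen=True)
class _PlacedPlant:
    plant: Plant
    codon_index: int


def _build_cds(
    rng: random.Random,
    codon_count: int,
    placed: Sequence[_PlacedPlant],
) -> str:
    cons = _Constraints()
    planted_idx = set()
    for pp in placed:
        plant, k = pp.plant, pp.codon_index
        planted_idx.add(k)
        if plant.decoy == "no_pam":
            if plant.codon == "TGG":
                _constrain_tgg_plant(cons, k, None, pam=False)
            else:
                _constrain_coding_plant(cons, plant.codon, k, None, pam=False)
        elif plant.decoy == "outside_window":
            # real NGG, but the C sits at -12: outside even the extended window
            _constrain_coding_plant(cons, plant.codon, k, -12, pam=True)
        elif plant.codon == "TGG":
            _constrain_tgg_plant(cons, k, plant.window_position, pam=True)
        else:
            _constrain_coding_plant(cons, plant.codon, k, plant.window_position,
                                    pam=True)

    codons = ["ATG"]
    for m in range(1, codon_count - 1):
        positions = [3 * m, 3 * m + 1, 3 * m + 2]
        if all(p in cons.eq for p in positions):
            codons.append("".join(cons.eq[p] for p in positions))
            if m not in planted_idx and codons[-1] in _FORBIDDEN_RANDOM:
                raise FixtureError(f"constraints force forbidden codon at {m}")
            continue
        for _ in range(300):
            codon = "".join(rng.choice(cons.choices(p)) for p in positions)
            if codon not in _FORBIDDEN_RANDOM:
                codons.append(codon)
                break
        else:
            raise FixtureError(f"cannot satisfy constraints at codon {m}")
    codons.append(rng.choice(_STOPS))
    if len(codons) != codon_count:
        raise FixtureError("codon bookkeeping error")
    return "".join(codons)


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def _plant_geometry(
    plant: Plant, k: int, cds: str
) -> tuple[str, int, str, str, tuple[int, ...], tuple[str, ...]]:
    """(locus strand, locus start, spacer, pam, editable positions, stops)
    of the intended site, in CDS-local coding orientation."""
    c = 3 * k
    if plant.decoy == "no_pam":
        return ("+", -1, "", "", (), ())
    if plant.decoy == "outside_window":
        a = c - 8  # window position -12 -> spacer index 8
        return ("+", a, cds[a : a + 20], cds[a + 20 : a + 23], (-12,), ())
    p = plant.window_position
    if plant.codon == "TGG":
        t = (c + 1) + p - 2
        spacer = _revcomp(cds[t + 3 : t + 23])
        pam = _revcomp(cds[t : t + 3])
        return ("-", t, spacer, pam, (p - 1, p), ("TGA", "TAG", "TAA"))
    a = c - (p + 20)
    spacer = cds[a : a + 20]
    pam = cds[a + 20 : a + 23]
    stop = {"CGA": "TGA", "CAG": "TAG", "CAA": "TAA"}.get(plant.codon, "")
    stops = (stop,) if plant.decoy is None else ()
    return ("+", a, spacer, pam, (p,), stops)


def _auto_plants(rng: random.Random, n_genes: int) -> list[Plant]:
    plants: list[Plant] = []
    for g in range(n_genes):
        n = rng.choices((0, 1, 2, 3), weights=(15, 35, 30, 20))[0]
        for _ in range(n):
            codon = rng.choice(PRE_STOP_CODONS)
            lo = -19 if codon == "TGG" else -20
            plants.append(Plant(codon, rng.randint(lo, -13), gene=g))
        if rng.random() < 0.2:
            kind = rng.choice(DECOY_KINDS)
            codon = "CGG" if kind == "non_prestop" else rng.choice(PRE_STOP_CODONS)
            pos = None if kind == "no_pam" else (
                rng.randint(-19 if codon == "TGG" else -20, -13)
            )
            if kind == "outside_window":
                codon = rng.choice(("CGA", "CAG", "CAA"))
            plants.append(Plant(codon, pos, gene=g, decoy=kind))
    return plants


def make_genome(
    n_genes: int,
    seed: int,
    plants: Sequence[Plant] | None = None,
    *,
    n_contigs: int = 1,
    codon_count_range: tuple[int, int] = (60, 140),
    intergenic_range: tuple[int, int] = (80, 160),
    duplicate_spacer_count: int = 0,
    self_check: bool = True,
) -> tuple[str, str, FixtureManifest]:
    """Build a synthetic genome; returns (FASTA text, GFF3 text, manifest).

    Deterministic in ``seed``.  With ``plants=None`` a random plant set is
    drawn (0-3 targets per gene plus occasional decoys).  ``self_check``
    reruns the brute-force oracle on the emitted genome and verifies it
    reproduces exactly the manifest's expected guide set.
    """
    if n_genes < 0:
        raise FixtureError("n_genes must be non-negative")
    rng = random.Random(seed)
    if plants is None:
        plants = _auto_plants(rng, n_genes)
    if plants and n_genes == 0:
        raise FixtureError("plants requested but n_genes is 0")
    by_gene: dict[int, list[Plant]] = {g: [] for g in range(n_genes)}
    unassigned = []
    for plant in plants:
        if plant.gene is None:
            unassigned.append(plant)
        elif plant.gene not in by_gene:
            raise FixtureError(f"plant references gene {plant.gene} of {n_genes}")
        else:
            by_gene[plant.gene].append(plant)
    for i, plant in enumerate(unassigned):
        by_gene[i % n_genes].append(plant)

    gene_specs = []  # (gene_id, contig_idx, strand, cds, placed plants)
    for g in range(n_genes):
        gene_plants = by_gene[g]
        n_min = _MIN_PLANT_INDEX + _END_MARGIN + _MIN_PLANT_SPACING * max(
            len(gene_plants), 1
        )
        codon_count = rng.randint(max(codon_count_range[0], n_min),
                                  max(codon_count_range[1], n_min))
        # spread planted codons evenly with jitter, keeping the minimum
        # spacing so constraint footprints never overlap
        placed = []
        span = codon_count - _END_MARGIN - _MIN_PLANT_INDEX
        step = span // max(len(gene_plants), 1)
        for j, plant in enumerate(gene_plants):
            jitter = rng.randint(0, max(step - _MIN_PLANT_SPACING, 0))
            k = _MIN_PLANT_INDEX + j * step + jitter
            placed.append(_PlacedPlant(plant, k))
        cds = _build_cds(rng, codon_count, placed)
        strand = rng.choice("+-")
        gene_specs.append((f"g{g + 1:03d}", g % n_contigs, strand, cds, placed))

    def pad(extra: int = 0) -> str:
        return "".join(
            rng.choice("ACGT") for _ in range(rng.randint(*intergenic_range) + extra)
        )

    contig_parts: list[list[str]] = [[pad()] for _ in range(max(n_contigs, 1))]
    contig_pos: list[int] = [len(parts[0]) for parts in contig_parts]
    genes: list[GeneModel] = []
    manifest_genes: list[ManifestGene] = []
    planted_sites: list[PlantedSite] = []
    contig_ids = [f"c{i + 1}" for i in range(max(n_contigs, 1))]

    for gene_id, ci, strand, cds, placed in gene_specs:
        start = contig_pos[ci]
        length = len(cds)
        inserted = cds if strand == "+" else _revcomp(cds)
        contig_parts[ci].append(inserted)
        contig_parts[ci].append(pad())
        contig_pos[ci] = start + length + len(contig_parts[ci][-1])
        gene = GeneModel(gene_id, contig_ids[ci], strand,
                         ((start, start + length),))
        genes.append(gene)
        manifest_genes.append(
            ManifestGene(gene_id, contig_ids[ci], strand, start, start + length,
                         length // 3, cds)
        )
        for pp in placed:
            locus_strand, a, spacer, pam, positions, stops = _plant_geometry(
                pp.plant, pp.codon_index, cds
            )
            if a < 0:
                site_strand, site_start = "+", -1
            elif strand == "+":
                site_strand, site_start = locus_strand, start + a
            else:
                site_strand = "-" if locus_strand == "+" else "+"
                site_start = start + length - a - 23
            planted_sites.append(
                PlantedSite(
                    gene_id=gene_id,
                    contig_id=contig_ids[ci],
                    gene_strand=strand,
                    codon=pp.plant.codon,
                    codon_index=pp.codon_index,
                    editable_positions=positions,
                    stop_codons=stops,
                    site_strand=site_strand,
                    site_start=site_start,
                    spacer=spacer,
                    pam=pam,
                    decoy=pp.plant.decoy,
                )
            )

    duplicated: list[str] = []
    if duplicate_spacer_count:
        real = [p for p in planted_sites if p.decoy is None]
        if duplicate_spacer_count > len(real):
            raise FixtureError("more spacer duplicates requested than planted sites")
        for p in real[:duplicate_spacer_count]:
            contig_idx = contig_ids.index(p.contig_id)
            contig_parts[contig_idx].append(pad(30) + p.spacer + p.pam + pad(30))
            duplicated.append(p.spacer)

    records = [
        GenomeRecord(cid, "".join(parts))
        for cid, parts in zip(contig_ids, contig_parts)
    ]
    manifest = FixtureManifest(
        seed=seed,
        contig_lengths={r.contig_id: len(r) for r in records},
        genes=tuple(manifest_genes),
        planted=tuple(planted_sites),
        duplicated_spacers=tuple(duplicated),
    )
    fasta = write_fasta(records)
    gff = write_gff3(genes)

    if self_check and n_genes:
        found = brute_force_design(records, genes, window="extended",
                                   policy="any-subset")
        expected = manifest.expected_guides(range(-20, -12))
        if found != expected:
            raise FixtureError(
                "generator self-check failed: oracle disagrees with manifest "
                f"(extra={sorted(found - expected)[:3]}, "
                f"missing={sorted(expected - found)[:3]})"
            )
    return fasta, gff, manifest


# ---------------------------------------------------------------------------
# independent brute-force oracle (deliberately shares no code with guide_scan
# or stop_logic; everything below is written from the definitions)
# ---------------------------------------------------------------------------

_ORACLE_STOPS = {"TAA", "TAG", "TGA"}


def _oracle_first_stop(cds: str) -> int:
    for i in range(len(cds) // 3):
        if cds[3 * i : 3 * i + 3] in _ORACLE_STOPS:
            return i
    return len(cds) // 3


def _oracle_cds(seq: str, gene: GeneModel) -> str:
    parts = "".join(seq[s:e] for s, e in gene.cds_intervals)
    if gene.strand == "-":
        parts = parts[::-1].translate(str.maketrans("ACGTN", "TGCAN"))
    return parts


def _oracle_cds_parts(buf: list[str], gene: GeneModel) -> str:
    parts = "".join("".join(buf[s:e]) for s, e in gene.cds_intervals)
    if gene.strand == "-":
        parts = parts[::-1].translate(str.maketrans("ACGTN", "TGCAN"))
    return parts


def brute_force_design(
    genome: Sequence[GenomeRecord],
    genes: Sequence[GeneModel],
    window: str = "canonical",
    policy: str = "any-subset",
) -> set[tuple]:
    """Exhaustive edit-and-translate guide design for small genomes.

    Enumerates every 23-mer NGG occurrence on both strands; for each subset
    of window Cs allowed by the policy, applies the C.G->T.A edits to the
    genome string, re-extracts and translates every gene overlapping the
    edited positions, and reports (contig, strand, start, gene_id) for pairs
    acquiring a stop upstream of the native one.  Quadratic and slow on
    purpose; intended for genomes up to ~100 kb.
    """
    win = range(-20, -15) if window == "canonical" else range(-20, -12)
    if window not in ("canonical", "extended"):
        raise ValueError(f"unknown window mode {window!r}")
    if policy not in ("any-subset", "all-window-cs"):
        raise ValueError(f"unknown edit policy {policy!r}")

    results: set[tuple] = set()
    for record in genome:
        seq = record.sequence
        contig_genes = [
            g
            for g in genes
            if g.contig_id == record.contig_id
            and len(_oracle_cds(seq, g)) % 3 == 0
            and "N" not in _oracle_cds(seq, g)
        ]
        native = {g.gene_id: _oracle_first_stop(_oracle_cds(seq, g))
                  for g in contig_genes}
        buf = list(seq)  # mutable genome copy; edits applied then reverted
        for s in range(len(seq) - 22):
            chunk = seq[s : s + 23]
            if "N" in chunk:
                continue
            oriented = []  # (strand, [plus-strand coords of window Cs])
            if chunk[21] == "G" and chunk[22] == "G":
                coords = [s + 20 + p for p in win if seq[s + 20 + p] == "C"]
                oriented.append(("+", coords))
            if chunk[0] == "C" and chunk[1] == "C":
                # protospacer on the reverse strand: its C is a forward G
                coords = [s + 2 - p for p in win if seq[s + 2 - p] == "G"]
                oriented.append(("-", coords))
            for strand, coords in oriented:
                if not coords:
                    continue
                if policy == "all-window-cs":
                    subsets = [tuple(coords)]
                else:
                    subsets = [
                        combo
                        for r in range(1, len(coords) + 1)
                        for combo in itertools.combinations(coords, r)
                    ]
                sub = "T" if strand == "+" else "A"
                for subset in subsets:
                    for coord in subset:
                        buf[coord] = sub
                    for gene in contig_genes:
                        if not any(gene.contains(c) for c in subset):
                            continue
                        key = (record.contig_id, strand, s, gene.gene_id)
                        if key in results:
                            continue
                        cds = _oracle_cds_parts(buf, gene)
                        if _oracle_first_stop(cds) < native[gene.gene_id]:
                            results.add(key)
                    for coord in subset:
                        buf[coord] = seq[coord]
    return results
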