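"""Enumeration of SpCas9 protospacers (20-nt spacer + NGG PAM) on both strands.

Positions follow the deaminase-editor convention: the NGG PAM occupies
positions 0..2 and the spacer positions -20 (PAM-distal, 5') .. -1
(PAM-proximal).  The cytidine-deaminase editing window is the PAM-distal
end of the spacer: canonically positions -20..-16, with efficient editing
observed out to -14 and weak editing at -13, hence the extended option.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

from .genome_model import GenomeRecord, revcomp

SITE_LENGTH = 23  # 20-nt spacer + 3-nt PAM

CANONICAL_POSITIONS = frozenset(range(-20, -15))  # -20..-16
EXTENDED_POSITIONS = frozenset(range(-20, -12))  # -20..-13


@dataclass(frozen=True)
class EditWindow:
    """The set of spacer positions where deamination is considered active."""

    mode: str
    positions: frozenset[int]

    def __post_init__(self) -> None:
        if not all(-20 <= p <= -1 for p in self.positions):
            raise ValueError("window positions must lie in -20..-1")

    @classmethod
    def canonical(cls) -> "EditWindow":
        return cls("canonical", CANONICAL_POSITIONS)

    @classmethod
    def extended(cls) -> "EditWindow":
        return cls("extended", EXTENDED_POSITIONS)

    @classmethod
    def from_mode(cls, mode: str) -> "EditWindow":
        try:
            return {"canonical": cls.canonical, "extended": cls.extended}[mode]()
        except KeyError:
            raise ValueError(f"unknown window mode {mode!r}") from None


@dataclass(frozen=True)
class ProtospacerSite:
    """A protospacer + PAM occurrence.

    ``start`` is the 0-based forward-strand coordinate of the 23-nt span
    (spacer + PAM in forward orientation for '+' sites; PAM-first reverse
    complement for '-' sites).  ``spacer`` and ``pam`` are always given in
    protospacer (5'->3') orientation.
    """

    contig_id: str
    strand: str
    start: int
    spacer: str
    pam: str

    def __post_init__(self) -> None:
        if len(self.spacer) != 20 or len(self.pam) != 3:
            raise ValueError("spacer must be 20 nt and PAM 3 nt")
        if self.pam[1] != "G" or self.pam[2] != "G":
            raise ValueError(f"PAM {self.pam!r} does not match NGG")

    @property
    def end(self) -> int:
        return self.start + SITE_LENGTH

    def genome_coord(self, position: int) -> int:
        """Forward-strand genome coordinate of spacer position -20..-1 or PAM
        position 0..2."""
        if not -20 <= position <= 2:
            raise ValueError(f"position {position} outside -20..2")
        if self.strand == "+":
            return self.start + 20 + position
        return self.start + 2 - position

    @property
    def genome_coords(self) -> dict[int, int]:
        return {p: self.genome_coord(p) for p in range(-20, 3)}

    def spacer_base(self, position: int) -> str:
        if not -20 <= position <= -1:
            raise ValueError(f"spacer position {position} outside -20..-1")
        return self.spacer[position + 20]


def find_pam_sites(
    record: GenomeRecord, *, circular: bool | None = None
) -> list[ProtospacerSite]:
    """All N20-NGG occurrences on both strands of a contig.

    A '+' site is a forward match N20-NGG; a '-' site is a forward-strand
    occurrence of CCN-N20 (protospacer on the reverse strand).  Sites whose
    23-nt span contains N are dropped.  With ``circular`` the scan wraps
    across the origin (sites get a start within [0, len); coordinates from
    :meth:`ProtospacerSite.genome_coord` are reduced modulo the length by the
    caller when needed).
    """
    if circular is None:
        circular = record.topology == "circular"
    seq = record.sequence
    n = len(seq)
    scan = seq + seq[: SITE_LENGTH - 1] if circular and n >= SITE_LENGTH else seq
    sites: list[ProtospacerSite] = []
    for s in range(min(len(scan) - SITE_LENGTH + 1, n)):
        chunk = scan[s : s + SITE_LENGTH]
        if "N" in chunk:
            continue
        if chunk[21] == "G" and chunk[22] == "G":
            sites.append(
                ProtospacerSite(record.contig_id, "+", s, chunk[:20], chunk[20:])
            )
        if chunk[0] == "C" and chunk[1] == "C":
            rc = revcomp(chunk)
            sites.append(
                ProtospacerSite(record.contig_id, "-", s, rc[:20], rc[20:])
            )
    return sites


def editable_cs(
    site: ProtospacerSite, window: EditWindow
) -> list[tuple[int, int]]:
    """Window positions whose spacer base is C, as (position, genome coord),
    ordered 5'->3' along the protospacer."""
    return [
        (p, site.genome_coord(p))
        for p in sorted(window.positions)
        if site.spacer_base(p) == "C"
    ]


def iter_sites(
    genome: list[GenomeRecord], *, circular: bool | None = None
) -> Iterator[ProtospacerSite]:
    for record in genome:
        yield from find_pam_sites(record, circular=circular)
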