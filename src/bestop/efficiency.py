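"""Sanger-trace base-editing efficiencies from per-position base signals.

Input is a per-position table of A/C/G/T peak signals for an amplicon
(EditR-style output: position, reference base, four signal columns).  For a
target C, the C-to-T efficiency is the occurrence frequency of T among the
four signals, T/(A+T+C+G), and the C-to-G efficiency is G/(A+T+C+G).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

BASES = ("A", "C", "G", "T")
TABLE_COLUMNS = ["position", "ref", "A", "C", "G", "T"]


class EfficiencyError(ValueError):
    """Raised on malformed frequency tables or invalid targets."""


@dataclass(frozen=True)
class EfficiencyResult:
    position: int
    reference_base: str
    ct_efficiency: float
    cg_efficiency: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.ct_efficiency <= 1.0:
            raise EfficiencyError("ct_efficiency outside [0, 1]")
        if not 0.0 <= self.cg_efficiency <= 1.0:
            raise EfficiencyError("cg_efficiency outside [0, 1]")
        if self.ct_efficiency + self.cg_efficiency > 1.0 + 1e-9:
            raise EfficiencyError("ct + cg efficiencies exceed 1")


def load_table(source) -> pd.DataFrame:
    """Read a TSV with columns position, ref, A, C, G, T and validate it.

    Positions are 1-based along the amplicon and must be strictly
    increasing; every row needs at least one positive signal.
    """
    table = pd.read_csv(source, sep="\t")
    missing = set(TABLE_COLUMNS) - set(table.columns)
    if missing:
        raise EfficiencyError(f"missing columns {sorted(missing)}")
    table = table[TABLE_COLUMNS].copy()
    table["ref"] = table["ref"].astype(str).str.upper()
    if not table["ref"].isin(BASES).all():
        raise EfficiencyError("reference base must be one of A/C/G/T")
    for base in BASES:
        if (table[base] < 0).any():
            raise EfficiencyError(f"negative signal in column {base}")
    if (table[list(BASES)].sum(axis=1) <= 0).any():
        raise EfficiencyError("row with zero total signal")
    positions = table["position"].to_numpy()
    if not (positions[1:] > positions[:-1]).all():
        raise EfficiencyError("positions must be strictly increasing")
    return table


def _signals(row: Mapping) -> tuple[float, float, float, float]:
    try:
        a, c, g, t = (float(row[b]) for b in BASES)
    except KeyError as exc:
        raise EfficiencyError(f"row missing signal column {exc}") from None
    if min(a, c, g, t) < 0:
        raise EfficiencyError("negative signal")
    if a + c + g + t <= 0:
        raise EfficiencyError("zero total signal")
    return a, c, g, t


def ct_efficiency(row: Mapping) -> float:
    """C-to-T efficiency of one row: T / (A + T + C + G)."""
    a, c, g, t = _signals(row)
    return t / (a + c + g + t)


def cg_efficiency(row: Mapping) -> float:
    """C-to-G efficiency of one row: G / (A + T + C + G)."""
    a, c, g, t = _signals(row)
    return g / (a + c + g + t)


def profile_target(
    table: pd.DataFrame, target_positions: Sequence[int]
) -> list[EfficiencyResult]:
    """Efficiencies at the given 1-based target positions, in input order.

    Targets must exist in the table and have reference base C (the metric is
    defined for deaminated cytosines).
    """
    by_position = {int(r["position"]): r for _, r in table.iterrows()}
    results = []
    for pos in target_positions:
        row = by_position.get(int(pos))
        if row is None:
            raise EfficiencyError(f"position {pos} absent from table")
        if str(row["ref"]).upper() != "C":
            raise EfficiencyError(
                f"position {pos} has reference base {row['ref']!r}, not C"
            )
        results.append(
            EfficiencyResult(
                position=int(pos),
                reference_base="C",
                ct_efficiency=ct_efficiency(row),
                cg_efficiency=cg_efficiency(row),
            )
        )
    return results


def results_to_frame(results: Iterable[EfficiencyResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "position": r.position,
                "ref": r.reference_base,
                "ct_efficiency": round(r.ct_efficiency, 6),
                "cg_efficiency": round(r.cg_efficiency, 6),
            }
            for r in results
        ],
        columns=["position", "ref", "ct_efficiency", "cg_efficiency"],
    )
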