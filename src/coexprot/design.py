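"""Experimental design: a 2 (condition) x 2 (day) x 5 (ear zone) factorial.

The study design crosses watering condition (well-watered WW vs water
deficit WD) with sampling day (silk emergence SE vs five days later SE5)
and five zones along the maize ear (1 = base, oldest ovaries; 5 = tip,
youngest). The cell (WD, SE5, zone 5) is absent: under water deficit the
ovaries at the tip of the ear abort before the second sampling day.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

CONDITIONS: tuple[str, str] = ("WW", "WD")
DAYS: tuple[str, str] = ("SE", "SE5")
ZONES: tuple[int, ...] = (1, 2, 3, 4, 5)

#: The design cell lost to ovary abortion (condition, day, zone).
DROPPED_CELL: tuple[str, str, int] = ("WD", "SE5", 5)

DESIGN_COLUMNS = ("condition", "day", "zone", "replicate")


@dataclass(frozen=True)
class SampleDesign:
    """One biological sample and its position in the factorial design."""

    sample_id: str
    condition: str
    day: str
    zone: int
    replicate: int

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.day not in DAYS:
            raise ValueError(f"unknown day {self.day!r}")
        if self.zone not in ZONES:
            raise ValueError(f"zone must be in 1..5, got {self.zone}")
        if self.replicate < 1:
            raise ValueError(f"replicate must be >= 1, got {self.replicate}")

    @property
    def cell(self) -> tuple[str, str, int]:
        return (self.condition, self.day, self.zone)


def generate_design(n_replicates: int = 3, drop_cell: bool = True) -> list[SampleDesign]:
    """Full factorial sample list, optionally without the aborted cell.

    With ``n_replicates=3`` and ``drop_cell=True`` this reproduces the
    study layout: 19 cells x 3 replicates = 57 samples.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    samples = []
    for cond in CONDITIONS:
        for day in DAYS:
            for zone in ZONES:
                if drop_cell and (cond, day, zone) == DROPPED_CELL:
                    continue
                for rep in range(1, n_replicates + 1):
                    samples.append(
                        SampleDesign(
                            sample_id=f"{cond}_{day}_z{zone}_r{rep}",
                            condition=cond,
                            day=day,
                            zone=zone,
                            replicate=rep,
                        )
                    )
    return samples


def design_frame(samples: Iterable[SampleDesign]) -> pd.DataFrame:
    """Tabulate samples as a DataFrame indexed by sample id."""
    rows = list(samples)
    ids = [s.sample_id for s in rows]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicated sample_id in design")
    frame = pd.DataFrame(
        {
            "condition": [s.condition for s in rows],
            "day": [s.day for s in rows],
            "zone": [s.zone for s in rows],
            "replicate": [s.replicate for s in rows],
        },
        index=pd.Index(ids, name="sample_id"),
    )
    return frame


def samples_from_frame(frame: pd.DataFrame) -> list[SampleDesign]:
    """Inverse of :func:`design_frame` (validates every row)."""
    return [
        SampleDesign(
            sample_id=str(idx),
            condition=str(row["condition"]),
            day=str(row["day"]),
            zone=int(row["zone"]),
            replicate=int(row["replicate"]),
        )
        for idx, row in frame.iterrows()
    ]


def validate_design(frame: pd.DataFrame, missing_cell_expected: bool = False) -> None:
    """Check factor levels and, when requested, the absence of the aborted cell."""
    samples_from_frame(frame)  # per-row validation
    if missing_cell_expected:
        cond, day, zone = DROPPED_CELL
        mask = (
            (frame["condition"] == cond)
            & (frame["day"] == day)
            & (frame["zone"] == zone)
        )
        if mask.any():
            raise ValueError(
                f"design declares cell {DROPPED_CELL} missing but "
                f"{int(mask.sum())} sample(s) belong to it"
            )


def design_cells(frame: pd.DataFrame) -> list[tuple[str, str, int]]:
    """Distinct (condition, day, zone) cells, in design order."""
    seen: dict[tuple[str, str, int], None] = {}
    for _, row in frame.iterrows():
        seen[(row["condition"], row["day"], int(row["zone"]))] = None
    return list(seen)
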