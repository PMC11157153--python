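"""Cross-sample alignment of detected mass shifts.

Fitted means from different samples (conditions and replicates alike)
that lie within a small mass window of each other are assumed to be the
same species and binned together; each bin's arithmetic mean mass is the
species mass used for PTM-pattern inference and reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mass_shift_detection import MassShift

__all__ = [
    "AlignedRow",
    "AlignedShiftTable",
    "bin_mass_shifts",
    "default_bin_size",
    "build_mass_shift_table",
]


@dataclass
class AlignedRow:
    """One binned species across samples."""

    average_mass: float
    average_shift: float
    members: list[MassShift] = field(default_factory=list)

    def abundance_by_sample(self) -> dict[str, float]:
        """Per-sample relative abundance (mean when a sample contributes
        more than one member, which a sane bin size makes rare)."""
        acc: dict[str, list[float]] = {}
        for m in self.members:
            acc.setdefault(m.sample_id, []).append(m.relative_abundance)
        return {k: float(np.mean(v)) for k, v in acc.items()}


@dataclass
class AlignedShiftTable:
    rows: list[AlignedRow] = field(default_factory=list)
    bin_size: float = 0.5

    def __len__(self) -> int:
        return len(self.rows)

    def sample_ids(self) -> list[str]:
        seen: list[str] = []
        for row in self.rows:
            for m in row.members:
                if m.sample_id not in seen:
                    seen.append(m.sample_id)
        return seen


def default_bin_size(mass_tolerance_ppm: float, reference_mass: float, floor: float = 0.5) -> float:
    """Bin size tied to the mass tolerance: ppm of the reference mass,
    never below 0.5 Da (the spacing quoted for replicate alignment)."""
    return max(mass_tolerance_ppm * 1e-6 * reference_mass, floor)


def bin_mass_shifts(shifts: list[MassShift], bin_size: float = 0.5) -> AlignedShiftTable:
    """Greedy left-to-right binning over means sorted ascending.

    A new bin starts when the candidate mean lies ``bin_size`` or more
    above the current bin's first (smallest) member, so a row's spread is
    always below ``bin_size``; this prevents the unbounded chaining plain
    single linkage would allow, keeps every member within ``bin_size`` of
    the row average, and yields the minimum possible number of rows for
    the given means (greedy interval covering).
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    table = AlignedShiftTable(bin_size=bin_size)
    if not shifts:
        return table
    ordered = sorted(shifts, key=lambda s: s.mean)
    current: list[MassShift] = [ordered[0]]

    def flush(members: list[MassShift]) -> None:
        avg_mass = float(np.mean([m.mean for m in members]))
        avg_shift = float(np.mean([m.shift for m in members]))
        table.rows.append(AlignedRow(avg_mass, avg_shift, members))

    for s in ordered[1:]:
        if s.mean - current[0].mean < bin_size:
            current.append(s)
        else:
            flush(current)
            current = [s]
    flush(current)
    return table


def build_mass_shift_table(table: AlignedShiftTable) -> pd.DataFrame:
    """Report rows: one species per row, sorted by ascending shift, with
    per-sample relative abundances (NaN where a sample lacks the species).
    PTM-pattern columns are joined onto this table downstream."""
    samples = table.sample_ids()
    records = []
    for row in sorted(table.rows, key=lambda r: r.average_shift):
        rec = {
            "average_mass_da": row.average_mass,
            "mass_shift_da": row.average_shift,
        }
        by_sample = row.abundance_by_sample()
        for s in samples:
            rec[f"rel_abundance[{s}]"] = by_sample.get(s, float("nan"))
        records.append(rec)
    columns = ["average_mass_da", "mass_shift_da"] + [f"rel_abundance[{s}]" for s in samples]
    return pd.DataFrame(records, columns=columns)
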