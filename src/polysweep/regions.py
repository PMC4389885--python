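"""Genomic window and region helpers shared by the scan modules.

All windows and regions are 0-based half-open; windows are anchored at
multiples of the step size starting at 0 on each chromosome.
"""
from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd


@dataclasses.dataclass
class SweepRegion:
    """A merged run of flagged windows from a named scan."""

    chrom: str
    start: int
    end: int
    source: str = "phs"
    n_windows: int = 1
    peak_value: float = float("nan")
    peak_pos: int | None = None
    peak_allele: str | None = None

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return self.chrom == chrom and self.start < end and start < self.end

    def to_bed_row(self) -> str:
        return (f"{self.chrom}\t{self.start}\t{self.end}\t{self.source}\t"
                f"{'' if np.isnan(self.peak_value) else round(self.peak_value, 6)}")


def windows_on(chrom_len: int, win_bp: int, step_bp: int | None = None
               ) -> np.ndarray:
    """Window starts covering [0, chrom_len)."""
    step = step_bp or win_bp
    return np.arange(0, max(chrom_len, 1), step, dtype=np.int64)


def merge_adjacent(flagged: pd.DataFrame, max_gap_bp: int = 0,
                   source: str = "scan",
                   value_col: str | None = "value") -> list[SweepRegion]:
    """Merge flagged windows (columns chrom, start, end) into maximal runs
    whose inter-window gap is <= max_gap_bp. Idempotent; output regions are
    pairwise disjoint per chromosome."""
    regions: list[SweepRegion] = []
    if len(flagged) == 0:
        return regions
    for chrom, sub in flagged.sort_values(["chrom", "start"]).groupby(
            "chrom", sort=False):
        cur = None
        for row in sub.itertuples(index=False):
            val = getattr(row, value_col, float("nan")) if value_col else float("nan")
            val = float(val) if val is not None and not pd.isna(val) else float("nan")
            if cur is None or row.start - cur.end > max_gap_bp:
                cur = SweepRegion(chrom, int(row.start), int(row.end), source,
                                  1, val)
                regions.append(cur)
            else:
                cur.end = max(cur.end, int(row.end))
                cur.n_windows += 1
                if not np.isnan(val) and (np.isnan(cur.peak_value)
                                          or val > cur.peak_value):
                    cur.peak_value = val
    return regions


def regions_to_bed(regions: list[SweepRegion], path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(r.to_bed_row() + "\n")


def read_bed_regions(path, source: str = "external") -> list[SweepRegion]:
    regions = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.rstrip("\n").split("\t")
            regions.append(SweepRegion(parts[0], int(parts[1]), int(parts[2]),
                                       source))
    return regions
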