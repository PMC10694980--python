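"""Region calling: top-quantile thresholding, proximity merging, bookkeeping."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GenomicRegion",
    "quantile_threshold",
    "merge_regions",
    "genome_fraction",
    "regions_to_frame",
    "regions_to_bed",
]


@dataclass(frozen=True)
class GenomicRegion:
    """A called region of merged windows (half-open bp coordinates)."""

    chrom: str
    start: int
    end: int
    n_windows: int
    mean_stat: float
    peak_stat: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("region end must exceed start")

    @property
    def length_bp(self) -> int:
        return self.end - self.start

    @property
    def length_kb(self) -> float:
        return self.length_bp / 1000.0


def quantile_threshold(
    windows: pd.DataFrame,
    values: np.ndarray,
    top_fraction: float = 0.005,
) -> tuple[float, np.ndarray]:
    """Genome-wide empirical top-quantile threshold.

    Returns ``(threshold, flags)`` where threshold is the (1 - top_fraction)
    quantile of the statistic over unmasked windows and flags marks windows
    with value >= threshold (ties at the threshold all included).
    """
    if len(windows) == 0:
        raise ValueError("empty window table")
    if not 0 < top_fraction < 1:
        raise ValueError("top_fraction must be in (0, 1)")
    values = np.asarray(values, dtype=float)
    mask = np.asarray(windows["masked"], dtype=bool) | np.isnan(values)
    usable = values[~mask]
    if usable.size == 0:
        raise ValueError("no unmasked windows")
    if usable.size < 1.0 / top_fraction:
        warnings.warn(
            f"only {usable.size} unmasked windows for top fraction {top_fraction}"
        )
    if np.all(usable == usable[0]):
        warnings.warn("statistic is constant; all unmasked windows flagged")
    threshold = float(np.quantile(usable, 1.0 - top_fraction))
    flags = np.zeros(len(windows), dtype=bool)
    flags[~mask] = values[~mask] >= threshold
    return threshold, flags


def merge_regions(
    windows: pd.DataFrame,
    flags: np.ndarray,
    merge_gap_bp: int = 200_000,
    values: np.ndarray | None = None,
) -> list[GenomicRegion]:
    """Merge flagged windows into regions.

    Consecutive flagged windows on the same chromosome whose edge gap
    (next.start - previous.end) is strictly less than ``merge_gap_bp`` are
    merged.  Masked windows inside a gap are transparent.  Region statistics
    aggregate member (flagged) windows only: mean and peak.
    """
    flags = np.asarray(flags, dtype=bool)
    values = (np.full(len(windows), np.nan)
              if values is None else np.asarray(values, dtype=float))
    out: list[GenomicRegion] = []
    flagged = windows.loc[flags].sort_values(["chrom", "start"], kind="stable")
    if flagged.empty:
        return out

    def _emit(chrom, start, end, members):
        vals = np.asarray(members, dtype=float)
        ok = ~np.isnan(vals)
        mean = float(vals[ok].mean()) if ok.any() else float("nan")
        peak = float(vals[ok].max()) if ok.any() else float("nan")
        out.append(GenomicRegion(chrom, int(start), int(end), len(members), mean, peak))

    cur = None
    for idx, row in flagged.iterrows():
        v = values[windows.index.get_loc(idx)]
        if cur is None:
            cur = [row["chrom"], row["start"], row["end"], [v]]
            continue
        same = row["chrom"] == cur[0]
        if same and (row["start"] - cur[2]) < merge_gap_bp:
            cur[2] = max(cur[2], row["end"])
            cur[3].append(v)
        else:
            _emit(*cur)
            cur = [row["chrom"], row["start"], row["end"], [v]]
    _emit(*cur)
    return out


def genome_fraction(
    regions: list[GenomicRegion], chrom_lengths: dict[str, int]
) -> float:
    """Total region length divided by total genome length."""
    total = sum(int(l) for l in chrom_lengths.values())
    if total <= 0:
        raise ValueError("genome length must be positive")
    covered = 0
    for r in regions:
        if r.chrom not in chrom_lengths:
            raise ValueError(f"region on unknown chromosome {r.chrom!r}")
        length = int(chrom_lengths[r.chrom])
        if r.start > length:
            raise ValueError(
                f"region {r.chrom}:{r.start}-{r.end} starts beyond chromosome end"
            )
        # windows tile past the chromosome end; clip the trailing overshoot
        covered += min(r.end, length + 1) - r.start
    return covered / total


def regions_to_frame(regions: list[GenomicRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.chrom, r.start, r.end, r.n_windows, r.mean_stat, r.peak_stat)
         for r in regions],
        columns=["chrom", "start", "end", "n_windows", "mean_stat", "peak_stat"],
    )


def regions_to_bed(regions: list[GenomicRegion], path) -> None:
    """Write regions as 0-based half-open BED3+."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end - 1}\t{r.mean_stat:.6g}\n")
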