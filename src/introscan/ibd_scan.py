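"""IBD segment detection and the per-bin nIBD/rIBD introgression statistics.

The detector is a deterministic seed-and-extend identity scan on phased
haplotypes: maximal runs of allele identity are merged across isolated
mismatches while the segment-wide mismatch rate stays below a tolerance.
Per 10 kb bin, nIBD = cIBD / tIBD where cIBD counts cross-group haplotype
pairs whose segment overlaps the bin and tIBD is the total number of
cross-group pairs; rIBD = nIBD_source - nIBD_control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import MISSING, HaplotypePanel, PopulationMap, make_windows

__all__ = [
    "IBDSegment",
    "detect_ibd_segments",
    "bin_ibd",
    "ribd",
    "ibd_sharing_table",
]


@dataclass(frozen=True)
class IBDSegment:
    """A shared-descent interval between two haplotypes (half-open bp)."""

    hap_a: str
    hap_b: str
    chrom: str
    start: int
    end: int
    n_snps: int
    mismatches: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("segment end must exceed start")
        if self.hap_a == self.hap_b:
            raise ValueError("segment endpoints must be distinct haplotypes")


def _greedy_merge_py(bounds: np.ndarray, rate: float) -> np.ndarray:
    """Merge identity runs across isolated mismatches, left to right.

    ``bounds`` = [-1, mismatch positions..., n_compared]; a run k spans
    [bounds[k]+1, bounds[k+1]) in compared-site index space.  Two adjacent
    runs are merged while total mismatches <= rate * total span.  Returns an
    (n, 4) array of (lo, hi, n_snps, mismatches), hi exclusive.
    """
    nb = len(bounds) - 1
    out = np.empty((nb, 4), dtype=np.int64)
    m = 0
    cur_lo = -1
    cur_hi = -1
    cur_mm = 0
    for k in range(nb):
        lo = bounds[k] + 1
        hi = bounds[k + 1]
        if hi <= lo:
            continue
        if cur_lo < 0:
            cur_lo, cur_hi, cur_mm = lo, hi, 0
            continue
        gap_mm = lo - cur_hi
        mm_total = cur_mm + gap_mm
        if mm_total <= rate * (hi - cur_lo):
            cur_hi, cur_mm = hi, mm_total
        else:
            out[m, 0] = cur_lo
            out[m, 1] = cur_hi
            out[m, 2] = cur_hi - cur_lo - cur_mm
            out[m, 3] = cur_mm
            m += 1
            cur_lo, cur_hi, cur_mm = lo, hi, 0
    if cur_lo >= 0:
        out[m, 0] = cur_lo
        out[m, 1] = cur_hi
        out[m, 2] = cur_hi - cur_lo - cur_mm
        out[m, 3] = cur_mm
        m += 1
    return out[:m]


try:  # pragma: no cover - exercised indirectly
    from numba import njit

    _greedy_merge = njit(cache=True)(_greedy_merge_py)
except Exception:  # pragma: no cover
    _greedy_merge = _greedy_merge_py


def _pair_segments(
    a: np.ndarray,
    b: np.ndarray,
    max_mismatch_rate: float,
) -> list[tuple[int, int, int, int]]:
    """Seed-and-extend identity scan for one haplotype pair on one chromosome.

    Returns (first_idx, last_idx, n_snps, mismatches) tuples where indices
    refer to panel variant columns (chromosome-local).
    """
    valid = (a != MISSING) & (b != MISSING)
    idx = np.flatnonzero(valid)
    if idx.size == 0:
        return []
    mm_pos = np.flatnonzero(a[idx] != b[idx]).astype(np.int64)
    bounds = np.concatenate(
        (np.asarray([-1], dtype=np.int64), mm_pos,
         np.asarray([idx.size], dtype=np.int64))
    )
    segs = _greedy_merge(bounds, float(max_mismatch_rate))
    return [(int(idx[lo]), int(idx[hi - 1]), int(n), int(mm))
            for lo, hi, n, mm in segs]


def detect_ibd_segments(
    panel: HaplotypePanel,
    recipient_haps: list[str],
    donor_haps: list[str],
    min_kb: float = 150.0,
    min_snps: int = 100,
    max_mismatch_rate: float = 0.02,
) -> list[IBDSegment]:
    """Detect IBD segments for every recipient x donor haplotype pair.

    A segment is reported iff its physical span is >= ``min_kb`` kb AND it
    is supported by >= ``min_snps`` jointly non-missing compared sites.
    Detection is symmetric in the two haplotypes of a pair.
    """
    if min_kb <= 0:
        raise ValueError("min_kb must be positive")
    hap_index = {h: i for i, h in enumerate(panel.haplotype_ids)}
    for h in list(recipient_haps) + list(donor_haps):
        if h not in hap_index:
            raise KeyError(f"unknown haplotype id {h!r}")

    min_bp = int(min_kb * 1000)
    out: list[IBDSegment] = []
    for chrom in panel.chromosomes():
        cmask = panel.chrom == chrom
        cpos = panel.pos[cmask]
        sub = panel.alleles[:, cmask]
        for ha in recipient_haps:
            ra = sub[hap_index[ha]]
            for hb in donor_haps:
                if ha == hb:
                    continue
                segs = _pair_segments(ra, sub[hap_index[hb]], max_mismatch_rate)
                for lo, hi, n, mm in segs:
                    start = int(cpos[lo])
                    end = int(cpos[hi]) + 1
                    if end - start >= min_bp and n >= min_snps:
                        out.append(
                            IBDSegment(ha, hb, chrom, start, end, int(n), int(mm))
                        )
    return out


def segments_to_frame(segments: list[IBDSegment]) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.hap_a, s.hap_b, s.chrom, s.start, s.end, s.n_snps, s.mismatches)
         for s in segments],
        columns=["hap_a", "hap_b", "chrom", "start", "end", "n_snps", "mismatches"],
    )


def bin_ibd(
    segments: list[IBDSegment],
    bins: pd.DataFrame,
    recipient_haps: list[str],
    donor_haps: list[str],
) -> pd.DataFrame:
    """Per-bin (cIBD, tIBD, nIBD) from a segment list.

    ``bins`` is a window table (``chrom, start, end`` half-open).  A pair
    counts toward cIBD in every bin its segment overlaps by >= 1 bp, at most
    once per bin.  tIBD = len(recipient_haps) * len(donor_haps) in all bins.
    """
    known = set(recipient_haps) | set(donor_haps)
    t_ibd = len(recipient_haps) * len(donor_haps)
    if t_ibd == 0:
        raise ValueError("empty haplotype sets")

    bin_starts = {c: g["start"].to_numpy() for c, g in bins.groupby("chrom", sort=False)}
    bin_offsets = {c: int(g.index[0]) for c, g in bins.groupby("chrom", sort=False)}
    bin_sizes = {c: g["end"].to_numpy() for c, g in bins.groupby("chrom", sort=False)}

    counts = np.zeros(len(bins), dtype=np.int64)
    by_pair: dict[tuple[str, str], set[int]] = {}
    for s in segments:
        if s.hap_a not in known or s.hap_b not in known:
            raise KeyError(f"segment references unknown haplotype: {s.hap_a}/{s.hap_b}")
        starts = bin_starts.get(s.chrom)
        if starts is None:
            continue
        ends = bin_sizes[s.chrom]
        # bins with start < seg.end and end > seg.start
        b0 = int(np.searchsorted(ends, s.start, side="right"))
        b1 = int(np.searchsorted(starts, s.end, side="left"))
        if b1 <= b0:
            continue
        off = bin_offsets[s.chrom]
        pair = (s.hap_a, s.hap_b) if s.hap_a <= s.hap_b else (s.hap_b, s.hap_a)
        covered = by_pair.setdefault(pair, set())
        for b in range(off + b0, off + b1):
            if b not in covered:
                covered.add(b)
                counts[b] += 1

    out = bins[["chrom", "start", "end"]].copy()
    out["cIBD"] = counts
    out["tIBD"] = t_ibd
    out["nIBD"] = counts / t_ibd
    return out


def ribd(nibd_source: np.ndarray, nibd_control: np.ndarray) -> np.ndarray:
    """rIBD = nIBD_source - nIBD_control per bin; bounded by [-1, 1]."""
    nibd_source = np.asarray(nibd_source, dtype=float)
    nibd_control = np.asarray(nibd_control, dtype=float)
    if nibd_source.shape != nibd_control.shape:
        raise ValueError("nIBD bin grids do not match")
    return nibd_source - nibd_control


def ibd_sharing_table(
    panel: HaplotypePanel,
    popmap: PopulationMap,
    recipient: str,
    source: str,
    control: str,
    bin_size: int = 10_000,
    min_kb: float = 150.0,
    min_snps: int = 100,
    max_mismatch_rate: float = 0.02,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """End-to-end rIBD scan: detect segments and build the per-bin table.

    Returns columns ``chrom bin_start bin_end cIBD_source tIBD_source
    nIBD_source cIBD_control tIBD_control nIBD_control rIBD``.
    """
    hap_ids = np.asarray(panel.haplotype_ids, dtype=object)
    rcp = list(hap_ids[panel.group_rows(popmap, recipient)])
    src = list(hap_ids[panel.group_rows(popmap, source)])
    ctl = list(hap_ids[panel.group_rows(popmap, control)])
    bins = make_windows(panel, bin_size, min_snps=1, chrom_lengths=chrom_lengths)

    table = bins[["chrom", "start", "end"]].rename(
        columns={"start": "bin_start", "end": "bin_end"}
    )
    for name, donors in (("source", src), ("control", ctl)):
        segs = detect_ibd_segments(
            panel, rcp, donors, min_kb=min_kb, min_snps=min_snps,
            max_mismatch_rate=max_mismatch_rate,
        )
        shared = bin_ibd(segs, bins, rcp, donors)
        table[f"cIBD_{name}"] = shared["cIBD"].to_numpy()
        table[f"tIBD_{name}"] = shared["tIBD"].to_numpy()
        table[f"nIBD_{name}"] = shared["nIBD"].to_numpy()
    table["rIBD"] = ribd(table["nIBD_source"].to_numpy(),
                         table["nIBD_control"].to_numpy())
    return table
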