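"""Phased genotype I/O, variant filtering and genomic windowing.

The central data structure is :class:`HaplotypePanel`: a (2*n_samples) x
n_variants matrix of phased alleles coded 0/1 with ``-1`` for missing.
Haplotype ``h`` of sample ``s`` lives at rows ``2s`` and ``2s+1``.
All scans operate on this panel plus a :class:`PopulationMap`.

Coordinates are 1-based inclusive in VCF I/O and half-open ``[start, end)``
for windows and regions internally; BED export converts to 0-based half-open.
"""

from __future__ import annotations

import dataclasses
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MISSING = np.int8(-1)

__all__ = [
    "MISSING",
    "HaplotypePanel",
    "PopulationMap",
    "VariantFilterConfig",
    "VcfParseError",
    "UnphasedGenotypeError",
    "load_phased_vcf",
    "write_vcf",
    "filter_variants",
    "make_windows",
    "parse_region",
]


class VcfParseError(ValueError):
    """Raised for malformed VCF input; message names the offending record."""


class UnphasedGenotypeError(ValueError):
    """Raised when phased input is required but unphased heterozygotes occur."""


@dataclass
class HaplotypePanel:
    """Phased alleles with per-variant chromosome/position metadata.

    Parameters
    ----------
    chrom : array of str, one label per variant.
    pos : array of int, 1-based physical positions, strictly increasing
        within each chromosome.
    alleles : int8 matrix of shape (2*n_samples, n_variants) with entries
        in {0, 1, -1}.
    sample_ids : sample names, one per pair of rows.
    variant_ids : unique variant identifiers.
    """

    chrom: np.ndarray
    pos: np.ndarray
    alleles: np.ndarray
    sample_ids: list[str]
    variant_ids: list[str]

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        self.sample_ids = list(self.sample_ids)
        self.variant_ids = list(self.variant_ids)
        self.validate()

    # -- invariants -----------------------------------------------------
    def validate(self) -> None:
        n_rows, n_var = self.alleles.shape
        if n_rows % 2 != 0:
            raise ValueError("allele matrix must have an even number of rows")
        if n_rows != 2 * len(self.sample_ids):
            raise ValueError("row count does not match 2 * n_samples")
        if n_var != len(self.pos) or n_var != len(self.chrom):
            raise ValueError("variant metadata length mismatch")
        if len(self.variant_ids) != n_var:
            raise ValueError("variant_ids length mismatch")
        if len(set(self.variant_ids)) != n_var:
            raise ValueError("variant_ids must be unique")
        bad = ~np.isin(self.alleles, (-1, 0, 1))
        if bad.any():
            raise ValueError("alleles must be in {0, 1, -1}")
        for c in self.chromosomes():
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {c}")

    # -- basic accessors ------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_variants(self) -> int:
        return self.alleles.shape[1]

    @property
    def is_empty(self) -> bool:
        return self.n_variants == 0

    @property
    def haplotype_ids(self) -> list[str]:
        return [f"{s}_{h}" for s in self.sample_ids for h in (1, 2)]

    def chromosomes(self) -> list[str]:
        """Chromosome labels in order of first appearance."""
        seen: dict[str, None] = {}
        for c in self.chrom:
            seen.setdefault(c, None)
        return list(seen)

    # -- subsetting -----------------------------------------------------
    def take_variants(self, idx: np.ndarray) -> "HaplotypePanel":
        idx = np.asarray(idx)
        return HaplotypePanel(
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            alleles=self.alleles[:, idx],
            sample_ids=self.sample_ids,
            variant_ids=[self.variant_ids[i] for i in np.atleast_1d(idx)],
        )

    def restrict(self, chrom: str, start: int, end: int) -> "HaplotypePanel":
        """Subset to variants with ``start <= pos < end`` on ``chrom``."""
        mask = (self.chrom == chrom) & (self.pos >= start) & (self.pos < end)
        return self.take_variants(np.flatnonzero(mask))

    def sample_rows(self, sample_id: str) -> tuple[int, int]:
        s = self.sample_ids.index(sample_id)
        return 2 * s, 2 * s + 1

    def group_rows(self, popmap: "PopulationMap", group: str) -> np.ndarray:
        """Haplotype row indices of all samples belonging to ``group``."""
        rows = []
        for i, s in enumerate(self.sample_ids):
            if popmap.group_of(s) == group:
                rows.extend((2 * i, 2 * i + 1))
        return np.asarray(rows, dtype=np.int64)


class PopulationMap:
    """sample_id -> group label mapping."""

    def __init__(self, mapping: dict[str, str]):
        self._map = dict(mapping)

    def group_of(self, sample_id: str) -> str:
        try:
            return self._map[sample_id]
        except KeyError:
            raise KeyError(f"sample {sample_id!r} absent from population map") from None

    def samples(self, group: str) -> list[str]:
        out = [s for s, g in self._map.items() if g == group]
        if not out:
            raise KeyError(f"no samples with group label {group!r}")
        return out

    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self._map.values():
            seen.setdefault(g, None)
        return list(seen)

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self._map

    def __len__(self) -> int:
        return len(self._map)

    def items(self):
        return self._map.items()

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PopulationMap":
        df = pd.read_csv(path, sep="\t", header=None, names=["sample_id", "group"],
                         dtype=str, comment="#")
        return cls(dict(zip(df["sample_id"], df["group"])))

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for s, g in self._map.items():
                fh.write(f"{s}\t{g}\n")

    def validate_panel(self, panel: HaplotypePanel) -> None:
        missing = [s for s in panel.sample_ids if s not in self]
        if missing:
            raise ValueError(f"samples missing from population map: {missing[:5]}")


@dataclass
class VariantFilterConfig:
    """Site-level QC thresholds.

    ``maf_min`` is strict (">" per convention: keep MAF strictly greater),
    ``max_missing`` is strict ("<": keep missing fraction strictly below).
    """

    maf_min: float = 0.05
    max_missing: float = 0.1
    biallelic_only: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.maf_min <= 0.5:
            raise ValueError("maf_min must be in [0, 0.5]")
        if not 0.0 <= self.max_missing <= 1.0:
            raise ValueError("max_missing must be in [0, 1]")


_REGION_RE = re.compile(r"^([^:]+):([\d,]+)-([\d,]+)$")


def parse_region(region: str) -> tuple[str, int, int]:
    """Parse ``chrom:start-end`` (1-based inclusive) into (chrom, start, end+1)."""
    m = _REGION_RE.match(region)
    if not m:
        raise ValueError(f"cannot parse region {region!r}; expected chrom:start-end")
    chrom = m.group(1)
    start = int(m.group(2).replace(",", ""))
    end = int(m.group(3).replace(",", ""))
    if end < start:
        raise ValueError(f"region end < start in {region!r}")
    return chrom, start, end + 1


def load_phased_vcf(
    path: str | Path,
    region: str | None = None,
    allow_unphased: bool = False,
) -> HaplotypePanel:
    """Read a VCF into a :class:`HaplotypePanel`.

    Only biallelic SNP records are retained (the panel cannot encode a third
    allele).  Unphased heterozygotes raise :class:`UnphasedGenotypeError`
    unless ``allow_unphased`` is set, in which case the written haplotype
    order is taken as given.
    """
    from cyvcf2 import VCF

    window = parse_region(region) if region is not None else None

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    if not sample_ids:
        raise VcfParseError(f"{path}: VCF contains no samples")

    chroms: list[str] = []
    positions: list[int] = []
    vids: list[str] = []
    cols: list[np.ndarray] = []
    for var in vcf:
        if window is not None:
            c, s, e = window
            if var.CHROM != c or not (s <= var.POS < e):
                continue
        if len(var.ALT) != 1:
            continue  # multiallelic / invariant records cannot be encoded
        gts = var.genotype.array()  # (n_samples, 3): allele_a, allele_b, phased
        if not allow_unphased:
            het = gts[:, 0] != gts[:, 1]
            unphased = (gts[:, 2] == 0) & het & (gts[:, 0] >= 0) & (gts[:, 1] >= 0)
            if unphased.any():
                bad = sample_ids[int(np.flatnonzero(unphased)[0])]
                raise UnphasedGenotypeError(
                    f"{path}: unphased heterozygote at {var.CHROM}:{var.POS} "
                    f"(sample {bad}); pass allow_unphased=True to accept"
                )
        col = gts[:, :2].astype(np.int8).reshape(-1)
        col[col < 0] = MISSING
        if (col > 1).any():
            raise VcfParseError(
                f"{path}: allele index > 1 at {var.CHROM}:{var.POS}"
            )
        chroms.append(var.CHROM)
        positions.append(var.POS)
        vid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        vids.append(vid)
        cols.append(col)
    vcf.close()

    if not cols:
        # empty-panel signal: zero-variant panel, not an error
        return HaplotypePanel(
            chrom=np.empty(0, dtype=object),
            pos=np.empty(0, dtype=np.int64),
            alleles=np.empty((2 * len(sample_ids), 0), dtype=np.int8),
            sample_ids=sample_ids,
            variant_ids=[],
        )
    alleles = np.column_stack(cols)
    return HaplotypePanel(
        chrom=np.asarray(chroms, dtype=object),
        pos=np.asarray(positions, dtype=np.int64),
        alleles=alleles,
        sample_ids=sample_ids,
        variant_ids=vids,
    )


def write_vcf(panel: HaplotypePanel, path: str | Path) -> None:
    """Write the panel as a minimal phased VCF 4.2 (REF=A, ALT=T placeholders)."""
    code = {0: "0", 1: "1", -1: "."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in panel.chromosomes():
            length = int(panel.pos[panel.chrom == c].max()) if panel.n_variants else 0
            fh.write(f"##contig=<ID={c},length={max(length, 1)}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(panel.sample_ids) + "\n")
        for j in range(panel.n_variants):
            col = panel.alleles[:, j]
            gts = "\t".join(
                f"{code[int(col[2 * s])]}|{code[int(col[2 * s + 1])]}"
                for s in range(panel.n_samples)
            )
            fh.write(
                f"{panel.chrom[j]}\t{panel.pos[j]}\t{panel.variant_ids[j]}"
                f"\tA\tT\t.\tPASS\t.\tGT\t{gts}\n"
            )


def filter_variants(
    panel: HaplotypePanel,
    cfg: VariantFilterConfig | None = None,
    with_stats: bool = False,
):
    """Apply site QC: MAF > maf_min, missing fraction < max_missing.

    Missing alleles are excluded from frequency denominators.  Order is
    preserved; the operation is idempotent.  With ``with_stats=True``
    returns ``(panel, stats)`` where stats counts removals per rule.
    """
    if cfg is None:
        cfg = VariantFilterConfig()
    if panel.is_empty:
        raise ValueError("cannot filter an empty panel")

    a = panel.alleles
    miss = a == MISSING
    n_obs = (~miss).sum(axis=0)
    n_alt = np.where(a == 1, 1, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_alt = np.where(n_obs > 0, n_alt / np.maximum(n_obs, 1), np.nan)
    maf = np.minimum(p_alt, 1.0 - p_alt)
    miss_frac = miss.sum(axis=0) / a.shape[0]

    all_missing = n_obs == 0
    fail_maf = all_missing | ~(maf > cfg.maf_min)
    fail_miss = ~(miss_frac < cfg.max_missing)
    keep = ~(fail_maf | fail_miss)

    stats = {
        "n_input": panel.n_variants,
        "removed_maf": int((fail_maf & ~fail_miss).sum()),
        "removed_missing": int((fail_miss & ~fail_maf).sum()),
        "removed_both": int((fail_maf & fail_miss).sum()),
        "n_kept": int(keep.sum()),
    }
    out = panel.take_variants(np.flatnonzero(keep))
    if stats["n_kept"] == 0:
        warnings.warn(f"all sites removed by variant filter: {stats}")
    if with_stats:
        return out, stats
    return out


def make_windows(
    panel: HaplotypePanel,
    size_bp: int,
    min_snps: int = 1,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Tile half-open windows of ``size_bp`` from position 1 of each chromosome.

    Returns a DataFrame with columns ``chrom, start, end, lo, hi, n_snps,
    masked``; ``lo:hi`` is the variant index span into the panel, and windows
    with fewer than ``min_snps`` variants are flagged masked (never dropped).
    Window spans partition each chromosome: every variant falls in exactly
    one window.
    """
    if size_bp <= 0:
        raise ValueError("size_bp must be positive")
    rows = []
    for c in panel.chromosomes():
        cmask = panel.chrom == c
        cpos = panel.pos[cmask]
        offset = int(np.flatnonzero(cmask)[0])
        length = int(cpos.max())
        if chrom_lengths and c in chrom_lengths:
            length = max(length, int(chrom_lengths[c]))
        n_win = int(np.ceil(length / size_bp))
        starts = 1 + size_bp * np.arange(n_win, dtype=np.int64)
        ends = starts + size_bp
        lo = np.searchsorted(cpos, starts, side="left") + offset
        hi = np.searchsorted(cpos, ends - 1, side="right") + offset
        for k in range(n_win):
            n = int(hi[k] - lo[k])
            rows.append(
                (c, int(starts[k]), int(ends[k]), int(lo[k]), int(hi[k]), n,
                 n < min_snps)
            )
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "lo", "hi", "n_snps", "masked"]
    )
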