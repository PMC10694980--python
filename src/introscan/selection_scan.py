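"""Windowed selection statistics: Hudson Fst, LSBL, Het/Zhet, Z-test masks."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_io import MISSING, HaplotypePanel, PopulationMap

__all__ = [
    "window_fst",
    "lsbl",
    "window_zhet",
    "z_significance",
    "hudson_site_components",
]

FST_CLAMP = (-0.05, 1.0)


def _group_counts(panel: HaplotypePanel, popmap: PopulationMap, group: str):
    rows = panel.group_rows(popmap, group)
    if rows.size < 2:
        raise ValueError(f"group {group!r} needs >= 2 haplotypes")
    a = panel.alleles[rows]
    n_obs = (a != MISSING).sum(axis=0).astype(float)
    n_ref = (a == 0).sum(axis=0).astype(float)
    return n_obs, n_ref


def hudson_site_components(
    pa: np.ndarray, pb: np.ndarray, na: np.ndarray, nb: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site numerator and denominator of the Hudson Fst estimator.

    N = (pa-pb)^2 - pa(1-pa)/(na-1) - pb(1-pb)/(nb-1);
    D = pa(1-pb) + pb(1-pa).  Sites with na<2, nb<2 or undefined
    frequencies yield NaN.
    """
    with np.errstate(invalid="ignore", divide="ignore"):
        num = (
            (pa - pb) ** 2
            - pa * (1.0 - pa) / (na - 1.0)
            - pb * (1.0 - pb) / (nb - 1.0)
        )
        den = pa * (1.0 - pb) + pb * (1.0 - pa)
    bad = (na < 2) | (nb < 2) | np.isnan(pa) | np.isnan(pb)
    num = np.where(bad, np.nan, num)
    den = np.where(bad, np.nan, den)
    return num, den


def window_fst(
    panel: HaplotypePanel,
    popmap: PopulationMap,
    group_a: str,
    group_b: str,
    windows: pd.DataFrame,
    clamp: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Hudson Fst per window as a ratio of summed site components.

    Returns ``(fst, fst_raw, mask)``: raw values are the unclamped ratio,
    reported values are clipped to [-0.05, 1]; windows without a usable
    site (or zero denominator) are masked.
    """
    na, ra = _group_counts(panel, popmap, group_a)
    nb, rb = _group_counts(panel, popmap, group_b)
    with np.errstate(invalid="ignore", divide="ignore"):
        pa = np.where(na > 0, ra / np.maximum(na, 1), np.nan)
        pb = np.where(nb > 0, rb / np.maximum(nb, 1), np.nan)
    num, den = hudson_site_components(pa, pb, na, nb)

    n_win = len(windows)
    raw = np.full(n_win, np.nan)
    mask = np.asarray(windows["masked"], dtype=bool).copy()
    lo = windows["lo"].to_numpy()
    hi = windows["hi"].to_numpy()
    for k in range(n_win):
        if mask[k]:
            continue
        wn = num[lo[k]:hi[k]]
        wd = den[lo[k]:hi[k]]
        ok = ~np.isnan(wn)
        if not ok.any() or np.nansum(wd[ok]) == 0:
            mask[k] = True
            continue
        raw[k] = np.sum(wn[ok]) / np.sum(wd[ok])
    fst = np.clip(raw, *FST_CLAMP) if clamp else raw.copy()
    return fst, raw, mask


def lsbl(
    fst_12: np.ndarray, fst_13: np.ndarray, fst_23: np.ndarray
) -> np.ndarray:
    """Locus-specific branch length of population 1:
    (Fst12 + Fst13 - Fst23) / 2, per window."""
    fst_12, fst_13, fst_23 = map(np.asarray, (fst_12, fst_13, fst_23))
    if not fst_12.shape == fst_13.shape == fst_23.shape:
        raise ValueError("Fst window grids do not match")
    return (fst_12 + fst_13 - fst_23) / 2.0


def window_zhet(
    panel: HaplotypePanel,
    popmap: PopulationMap,
    group: str,
    windows: pd.DataFrame,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Window heterozygosity and its genome-wide Z-standardization.

    Per site Het = 2p(1-p) with p the reference-allele frequency in the
    group; per window Het is the mean over usable sites, and Zhet is
    standardized by the mean and SD over all unmasked windows.  Returns
    ``(het, zhet, mask)``.
    """
    n_obs, n_ref = _group_counts(panel, popmap, group)
    with np.errstate(invalid="ignore"):
        p = np.where(n_obs > 0, n_ref / np.maximum(n_obs, 1), np.nan)
    site_het = 2.0 * p * (1.0 - p)

    n_win = len(windows)
    het = np.full(n_win, np.nan)
    mask = np.asarray(windows["masked"], dtype=bool).copy()
    lo = windows["lo"].to_numpy()
    hi = windows["hi"].to_numpy()
    for k in range(n_win):
        if mask[k]:
            continue
        w = site_het[lo[k]:hi[k]]
        ok = ~np.isnan(w)
        if not ok.any():
            mask[k] = True
            continue
        het[k] = w[ok].mean()

    zhet = np.full(n_win, np.nan)
    vals = het[~mask]
    if vals.size:
        sd = vals.std(ddof=0)
        if sd == 0:
            warnings.warn("window Het is constant; Zhet undefined")
        else:
            zhet[~mask] = (vals - vals.mean()) / sd
    return het, zhet, mask


def z_significance(
    values: np.ndarray,
    alpha: float = 0.05,
    tail: str = "upper",
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Z-test flags: standardize over unmasked windows and flag windows
    whose tail probability is < alpha.

    ``tail`` is "upper" or "lower" (one-sided, the default usage: high
    differentiation, low heterozygosity) or "both" (two-sided).
    """
    if tail not in ("upper", "lower", "both"):
        raise ValueError("tail must be 'upper', 'lower' or 'both'")
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.isnan(values)
    else:
        mask = np.asarray(mask, dtype=bool) | np.isnan(values)
    flags = np.zeros(values.shape, dtype=bool)
    vals = values[~mask]
    if vals.size < 2:
        raise ValueError("need >= 2 unmasked windows for a Z test")
    sd = vals.std(ddof=0)
    if sd == 0:
        warnings.warn("constant statistic; no windows flagged")
        return flags
    z = (values - vals.mean()) / sd
    with np.errstate(invalid="ignore"):
        if tail == "upper":
            p = stats.norm.sf(z)
        elif tail == "lower":
            p = stats.norm.cdf(z)
        else:
            p = 2.0 * stats.norm.sf(np.abs(z))
    flags[~mask] = p[~mask] < alpha
    return flags
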