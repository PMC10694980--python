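"""Haplotype-EBV association (one-way ANOVA) and expression utilities."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["AssociationResult", "anova_oneway", "fpkm", "per_gene_ttest"]


@dataclass
class AssociationResult:
    groups: list[tuple[str, int, float]]  # (label, n, mean)
    f: float
    df_between: int
    df_within: int
    p: float

    def summary(self) -> pd.DataFrame:
        df = pd.DataFrame(self.groups, columns=["group", "n", "mean"])
        df["f"] = self.f
        df["df_between"] = self.df_between
        df["df_within"] = self.df_within
        df["p"] = self.p
        return df


def anova_oneway(values, groups) -> AssociationResult:
    """Classical one-way ANOVA of ``values`` across genotype ``groups``.

    Empty groups are dropped with a warning (e.g. a genotype class absent
    from a population).  F = MS_between / MS_within with an F-distribution
    p-value.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups, dtype=object)
    ok = ~pd.isna(groups) & ~np.isnan(values)
    values, groups = values[ok], groups[ok]

    labels = [g for g in pd.unique(groups)]
    counts = {g: int((groups == g).sum()) for g in labels}
    empty = [g for g in labels if counts[g] == 0]
    if empty:
        warnings.warn(f"dropping empty groups: {empty}")
    labels = [g for g in labels if counts[g] > 0]
    if len(labels) < 2:
        raise ValueError("need >= 2 non-empty groups for ANOVA")

    arrays = [values[groups == g] for g in labels]
    n_total = sum(a.size for a in arrays)
    k = len(labels)
    if n_total - k < 1:
        raise ValueError("no within-group degrees of freedom")
    grand = values.mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_b, df_w = k - 1, n_total - k
    ms_b = ss_between / df_b
    ms_w = ss_within / df_w
    if ms_w == 0:
        f = np.inf if ms_b > 0 else 0.0
        p = 0.0 if ms_b > 0 else 1.0
    else:
        f = ms_b / ms_w
        p = float(stats.f.sf(f, df_b, df_w))
    sized = sorted(labels, key=lambda g: str(g))
    return AssociationResult(
        groups=[(str(g), int((groups == g).sum()), float(values[groups == g].mean()))
                for g in sized],
        f=float(f),
        df_between=df_b,
        df_within=df_w,
        p=p,
    )


def fpkm(
    counts: np.ndarray | pd.DataFrame,
    gene_lengths: np.ndarray,
    library_sizes: np.ndarray,
) -> np.ndarray | pd.DataFrame:
    """FPKM[g,s] = counts[g,s] / (length_kb[g] * library_size_millions[s])."""
    arr = np.asarray(counts, dtype=float)
    lengths = np.asarray(gene_lengths, dtype=float)
    libs = np.asarray(library_sizes, dtype=float)
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    if (libs <= 0).any():
        raise ValueError("library sizes must be positive")
    if arr.shape != (lengths.size, libs.size):
        raise ValueError("counts must be genes x samples")
    out = arr / (lengths[:, None] / 1000.0) / (libs[None, :] / 1e6)
    if isinstance(counts, pd.DataFrame):
        return pd.DataFrame(out, index=counts.index, columns=counts.columns)
    return out


def per_gene_ttest(
    fpkm_a: np.ndarray | pd.DataFrame,
    fpkm_b: np.ndarray | pd.DataFrame,
    welch: bool = False,
) -> pd.DataFrame:
    """Two-sided two-sample t-test per gene (Student pooled by default).

    Genes with zero variance in both groups and equal means get t=0, p=1.
    """
    a = np.asarray(fpkm_a, dtype=float)
    b = np.asarray(fpkm_b, dtype=float)
    if a.ndim != 2 or b.ndim != 2 or a.shape[0] != b.shape[0]:
        raise ValueError("inputs must be genes x samples with matching genes")
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("need >= 2 samples per group")
    t, p = stats.ttest_ind(a, b, axis=1, equal_var=not welch)
    degenerate = np.isnan(t)
    t = np.where(degenerate, 0.0, t)
    p = np.where(degenerate, 1.0, p)
    if degenerate.any():
        warnings.warn(f"{int(degenerate.sum())} genes with zero variance; p set to 1")
    index = fpkm_a.index if isinstance(fpkm_a, pd.DataFrame) else pd.RangeIndex(a.shape[0])
    return pd.DataFrame({"t": t, "p": p}, index=index)
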