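"""Population structure: allele frequencies, p-distances, NJ trees, PCA."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import MISSING, HaplotypePanel, PopulationMap

__all__ = [
    "DistanceMatrix",
    "allele_frequencies",
    "p_distance_matrix",
    "nj_tree",
    "pca",
]


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T, equal_nan=True):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("distance matrix diagonal must be zero")


def allele_frequencies(
    panel: HaplotypePanel, popmap: PopulationMap, group: str
) -> np.ndarray:
    """Per-site reference-allele (allele 0) frequency within ``group``.

    Missing alleles are excluded from the denominator; sites where the whole
    group is missing are returned as NaN.
    """
    rows = panel.group_rows(popmap, group)
    if rows.size == 0:
        raise KeyError(f"group {group!r} has no samples in the panel")
    a = panel.alleles[rows]
    n_obs = (a != MISSING).sum(axis=0)
    n_ref = (a == 0).sum(axis=0)
    with np.errstate(invalid="ignore"):
        p = np.where(n_obs > 0, n_ref / np.maximum(n_obs, 1), np.nan)
    return p


def p_distance_matrix(panel: HaplotypePanel, unit: str = "sample") -> DistanceMatrix:
    """Pairwise proportion-of-differences matrix.

    ``unit="haplotype"`` compares allele rows directly; ``unit="sample"``
    compares genotype dosages with |dosage_i - dosage_j| / 2 averaged over
    jointly non-missing sites (reduces to the haplotype definition for
    homozygous data).  Pairs with zero jointly non-missing sites get NaN.
    """
    if unit == "haplotype":
        mat = panel.alleles.astype(float)
        mat[panel.alleles == MISSING] = np.nan
        labels = panel.haplotype_ids
        scale = 1.0
    elif unit == "sample":
        a = panel.alleles.astype(float)
        a[panel.alleles == MISSING] = np.nan
        mat = a[0::2] + a[1::2]  # dosage of allele 1; nan if either hap missing
        labels = list(panel.sample_ids)
        scale = 2.0
    else:
        raise ValueError("unit must be 'sample' or 'haplotype'")

    n = mat.shape[0]
    if n < 2:
        raise ValueError("need at least 2 units for a distance matrix")
    d = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(mat[i] - mat[i + 1:]) / scale  # (n-i-1, m), nan where missing
        valid = ~np.isnan(diff)
        cnt = valid.sum(axis=1)
        with np.errstate(invalid="ignore"):
            row = np.where(cnt > 0, np.nansum(diff, axis=1) / np.maximum(cnt, 1), np.nan)
        d[i, i + 1:] = row
        d[i + 1:, i] = row
    if np.isnan(d).any():
        warnings.warn("some pairs share no non-missing sites; distances set to NaN")
    return DistanceMatrix(labels=labels, d=d)


def _newick_escape(label: str) -> str:
    if any(c in label for c in " ():,;"):
        return "'" + label.replace("'", "''") + "'"
    return label


def nj_tree(dm: DistanceMatrix) -> str:
    """Neighbor-joining (Saitou-Nei) tree as an unrooted Newick string.

    Ties in the Q criterion are broken by the lexicographically smallest
    label pair so output is deterministic.  Negative branch lengths are
    clamped to zero with a warning.
    """
    labels = list(dm.labels)
    n = len(labels)
    if n < 3:
        raise ValueError("need at least 3 taxa for an NJ tree")
    if np.isnan(dm.d).any():
        raise ValueError("distance matrix contains NaN entries")

    d = dm.d.astype(float).copy()
    nodes = [_newick_escape(l) for l in labels]
    names = list(labels)  # for tie-breaking
    clamped = False

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        cand = np.argwhere(np.isclose(q, qmin, rtol=0, atol=1e-12))
        cand = [(i, j) for i, j in cand if i < j]
        i, j = min(cand, key=lambda ij: tuple(sorted((names[ij[0]], names[ij[1]]))))
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        if li < 0 or lj < 0:
            clamped = True
        li, lj = max(li, 0.0), max(lj, 0.0)
        new = f"({nodes[i]}:{li:.10g},{nodes[j]}:{lj:.10g})"
        dnew = 0.5 * (d[i] + d[j] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d2 = np.empty((m - 1, m - 1))
        d2[:-1, :-1] = d[np.ix_(keep, keep)]
        d2[-1, :-1] = d2[:-1, -1] = dnew[keep]
        d2[-1, -1] = 0.0
        nodes = [nodes[k] for k in keep] + [new]
        names = [names[k] for k in keep] + [min(names[i], names[j])]
        d = d2

    # final trifurcation
    la = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
    lb = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
    lc = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
    if min(la, lb, lc) < 0:
        clamped = True
    la, lb, lc = (max(x, 0.0) for x in (la, lb, lc))
    if clamped:
        warnings.warn("negative NJ branch lengths clamped to 0")
    return f"({nodes[0]}:{la:.10g},{nodes[1]}:{lb:.10g},{nodes[2]}:{lc:.10g});"


def pca(
    panel: HaplotypePanel, n_components: int = 10, scale: bool = True
) -> tuple[pd.DataFrame, np.ndarray]:
    """Variance-standardized genotype PCA.

    Dosages (0/1/2 copies of allele 1) are centered per site, missing values
    imputed to the site mean, and columns scaled by sqrt(2p(1-p)) when
    ``scale`` is set.  Returns (scores DataFrame indexed by sample with
    columns PC1..PCk, explained variance array, nonincreasing).
    """
    if panel.n_samples < 2 or panel.n_variants < 2:
        raise ValueError("PCA needs at least 2 samples and 2 variants")
    a = panel.alleles.astype(float)
    a[panel.alleles == MISSING] = np.nan
    g = a[0::2] + a[1::2]  # (n_samples, m), nan where either hap missing
    col_mean = np.nanmean(g, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    inds = np.where(np.isnan(g))
    g[inds] = np.take(col_mean, inds[1])
    g -= col_mean
    if scale:
        p = col_mean / 2.0
        sd = np.sqrt(2.0 * p * (1.0 - p))
        nz = sd > 0
        g[:, nz] /= sd[nz]
        g[:, ~nz] = 0.0

    n = g.shape[0]
    u, s, _ = np.linalg.svd(g, full_matrices=False)
    k = min(n_components, len(s))
    scores = u[:, :k] * s[:k]
    explained = (s ** 2) / (n - 1)
    if np.allclose(explained, 0.0):
        warnings.warn("all components have zero variance (constant matrix)")
    df = pd.DataFrame(
        scores, index=pd.Index(panel.sample_ids, name="sample"),
        columns=[f"PC{i+1}" for i in range(k)],
    )
    return df, explained[:k]
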