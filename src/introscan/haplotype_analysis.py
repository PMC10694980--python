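"""Regional haplotype analysis.

Informative-SNP filtering, haplotype frequency tables, major/minor heat-map
recoding, minimum-spanning haplotype networks, tag-SNP selection and Q/q
introgression-genotype calling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import MISSING, HaplotypePanel, PopulationMap
from .popstruct import allele_frequencies

__all__ = [
    "RegionalHaplotypeSet",
    "HaplotypeNetwork",
    "NoTagSnpError",
    "informative_snps",
    "build_haplotype_set",
    "heatmap_matrix",
    "haplotype_network",
    "tag_snps",
    "call_Qq",
]


class NoTagSnpError(ValueError):
    """No site perfectly separates the Q haplotypes from the rest."""


@dataclass
class RegionalHaplotypeSet:
    """Distinct haplotypes over a region's (filtered) SNPs.

    ``alleles`` is a (n_distinct, n_snps) 0/1 matrix; labels are hap_1,
    hap_2, ... in descending total frequency (ties by first occurrence).
    ``carriers`` maps each label to the panel haplotype ids collapsed into
    it; ``group_counts`` is a label x group count table.
    """

    labels: list[str]
    alleles: np.ndarray
    total_counts: np.ndarray
    group_counts: pd.DataFrame
    carriers: dict[str, list[str]]
    variant_idx: np.ndarray
    n_excluded_missing: int = 0

    def allele_string(self, label: str) -> str:
        i = self.labels.index(label)
        return "".join(str(int(x)) for x in self.alleles[i])

    @property
    def n_haplotypes(self) -> int:
        return len(self.labels)


@dataclass
class HaplotypeNetwork:
    """Minimum spanning network over haplotype Hamming distances."""

    nodes: list[str]
    sizes: np.ndarray
    edges: list[tuple[str, str, int]]  # (hap_a, hap_b, hamming distance)

    @property
    def total_weight(self) -> int:
        return sum(w for _, _, w in self.edges)


def informative_snps(
    panel: HaplotypePanel,
    popmap: PopulationMap,
    group_a: str,
    group_b: str,
    min_abs_diff: float = 0.8,
) -> np.ndarray:
    """Variant indices where |p_groupA - p_groupB| > min_abs_diff."""
    pa = allele_frequencies(panel, popmap, group_a)
    pb = allele_frequencies(panel, popmap, group_b)
    with np.errstate(invalid="ignore"):
        keep = np.abs(pa - pb) > min_abs_diff
    keep &= ~np.isnan(pa) & ~np.isnan(pb)
    return np.flatnonzero(keep)


def build_haplotype_set(
    panel: HaplotypePanel,
    popmap: PopulationMap,
    region: tuple[str, int, int] | None = None,
    snps: np.ndarray | None = None,
) -> RegionalHaplotypeSet:
    """Collapse the region's haplotypes into distinct allele strings.

    Haplotypes with any missing allele in the region are excluded (counted
    in ``n_excluded_missing``).  Labels hap_1.. are assigned by descending
    total frequency, ties broken by first occurrence in panel row order.
    """
    sub = panel
    if region is not None:
        sub = panel.restrict(*region)
    if snps is not None:
        sub = sub.take_variants(np.asarray(snps))
    if sub.n_variants == 0:
        raise ValueError("region contains no SNPs after filtering")

    hap_ids = sub.haplotype_ids
    groups = [popmap.group_of(s) for s in sub.sample_ids for _ in (0, 1)]
    complete = ~(sub.alleles == MISSING).any(axis=1)
    n_excluded = int((~complete).sum())

    seen: dict[bytes, int] = {}
    order: list[np.ndarray] = []
    members: list[list[int]] = []
    for r in np.flatnonzero(complete):
        key = sub.alleles[r].tobytes()
        if key not in seen:
            seen[key] = len(order)
            order.append(sub.alleles[r].copy())
            members.append([])
        members[seen[key]].append(r)
    if not order:
        raise ValueError("no haplotype without missing data in the region")

    counts = np.array([len(m) for m in members])
    rank = sorted(range(len(order)), key=lambda i: (-counts[i], i))
    labels = [f"hap_{k + 1}" for k in range(len(rank))]
    alleles = np.vstack([order[i] for i in rank])
    total = counts[rank]

    group_labels = sorted(set(groups))
    gc = pd.DataFrame(0, index=labels, columns=group_labels, dtype=int)
    carriers: dict[str, list[str]] = {}
    for k, i in enumerate(rank):
        carriers[labels[k]] = [hap_ids[r] for r in members[i]]
        for r in members[i]:
            gc.loc[labels[k], groups[r]] += 1

    return RegionalHaplotypeSet(
        labels=labels,
        alleles=alleles,
        total_counts=total,
        group_counts=gc,
        carriers=carriers,
        variant_idx=np.arange(sub.n_variants) if snps is None else np.asarray(snps),
        n_excluded_missing=n_excluded,
    )


def major_haplotype(hset: RegionalHaplotypeSet, group: str) -> str:
    """Most frequent haplotype label within ``group`` (ties by hap rank)."""
    col = hset.group_counts[group]
    if col.sum() == 0:
        raise ValueError(f"group {group!r} carries no haplotype in the set")
    return col.idxmax()


def heatmap_matrix(
    hset: RegionalHaplotypeSet, reference_group: str
) -> pd.DataFrame:
    """Recode haplotype alleles as major(0)/minor(1) relative to a group.

    The per-site major allele is the more frequent allele among the
    reference group's haplotypes (ties resolved to allele 0).  Rows are
    haplotype labels in frequency order.
    """
    if reference_group not in hset.group_counts.columns:
        raise KeyError(f"unknown reference group {reference_group!r}")
    w = hset.group_counts[reference_group].to_numpy()
    if w.sum() == 0:
        raise ValueError(f"group {reference_group!r} carries no haplotypes")
    ones = (hset.alleles * w[:, None]).sum(axis=0)
    major = (ones * 2 > w.sum()).astype(np.int8)  # 1 iff allele 1 is majority
    coded = (hset.alleles != major[None, :]).astype(np.int8)
    return pd.DataFrame(
        coded, index=hset.labels,
        columns=[f"snp_{i}" for i in range(hset.alleles.shape[1])],
    )


def haplotype_network(hset: RegionalHaplotypeSet) -> HaplotypeNetwork:
    """Minimum spanning tree over pairwise Hamming distances (Kruskal).

    Deterministic: edges sorted by (weight, hap index pair).
    """
    n = hset.n_haplotypes
    if n < 2:
        raise ValueError("need >= 2 haplotypes for a network")
    a = hset.alleles
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            w = int((a[i] != a[j]).sum())
            edges.append((w, i, j))
    edges.sort()

    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    mst = []
    for w, i, j in edges:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
            mst.append((hset.labels[i], hset.labels[j], w))
            if len(mst) == n - 1:
                break
    return HaplotypeNetwork(
        nodes=list(hset.labels), sizes=hset.total_counts.copy(), edges=mst
    )


def tag_snps(
    hset: RegionalHaplotypeSet,
    q_haplotypes: set[str] | list[str],
    n_tags: int = 2,
    seed: int = 0,
) -> np.ndarray:
    """Randomly pick ``n_tags`` sites that perfectly separate Q from q.

    A separating site is one where every haplotype in ``q_haplotypes``
    carries one allele and every other haplotype carries the other.
    Returned indices refer to the haplotype set's SNP columns (and map to
    panel variants via ``hset.variant_idx``).
    """
    q_set = set(q_haplotypes)
    if not q_set:
        raise ValueError("q_haplotypes must be non-empty")
    unknown = q_set - set(hset.labels)
    if unknown:
        raise KeyError(f"unknown haplotype labels: {sorted(unknown)}")
    if q_set == set(hset.labels):
        raise ValueError("q_haplotypes must be a strict subset of haplotypes")

    in_q = np.array([l in q_set for l in hset.labels])
    aq = hset.alleles[in_q]
    ao = hset.alleles[~in_q]
    q_fixed0 = (aq == 0).all(axis=0) & (ao == 1).all(axis=0)
    q_fixed1 = (aq == 1).all(axis=0) & (ao == 0).all(axis=0)
    separating = np.flatnonzero(q_fixed0 | q_fixed1)
    if separating.size < n_tags:
        best = np.abs(aq.mean(axis=0) - ao.mean(axis=0))
        top = np.argsort(-best)[:5]
        raise NoTagSnpError(
            f"only {separating.size} perfectly separating sites "
            f"(need {n_tags}); best |freq diff| sites: "
            + ", ".join(f"snp_{i} ({best[i]:.2f})" for i in top)
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(separating, size=n_tags, replace=False)
    return np.sort(chosen)


def call_Qq(
    panel: HaplotypePanel,
    tag_variant_idx: np.ndarray,
    q_allele_pattern: np.ndarray,
) -> pd.DataFrame:
    """Genotype each individual as QQ/Qq/qq from tag-SNP alleles.

    A haplotype is Q iff it matches ``q_allele_pattern`` at every tag site.
    Individuals with any missing tag allele are no-calls (genotype NA).
    """
    tag_variant_idx = np.asarray(tag_variant_idx)
    q_allele_pattern = np.asarray(q_allele_pattern, dtype=np.int8)
    if tag_variant_idx.shape != q_allele_pattern.shape:
        raise ValueError("tag index and allele pattern lengths differ")
    sub = panel.alleles[:, tag_variant_idx]
    rows = []
    for s, sample in enumerate(panel.sample_ids):
        h1, h2 = sub[2 * s], sub[2 * s + 1]
        if (h1 == MISSING).any() or (h2 == MISSING).any():
            rows.append((sample, pd.NA))
            continue
        n_q = int((h1 == q_allele_pattern).all()) + int((h2 == q_allele_pattern).all())
        rows.append((sample, ("qq", "Qq", "QQ")[n_q]))
    return pd.DataFrame(rows, columns=["individual", "genotype"])
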