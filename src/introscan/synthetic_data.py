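"""Synthetic phased panels and pedigreed phenotypes with known ground truth.

Panels are built from allele-frequency profiles rather than a coalescent:
a control pool and a diverged source pool are drawn site-wise, recipients
are crossover mosaics of control haplotypes, and introgressed tracts are
planted by copying source haplotypes into a configurable fraction of
recipient haplotypes.  This creates exactly the IBD-sharing and
differentiation structure the scans consume, with full truth bookkeeping.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .genotype_io import MISSING, HaplotypePanel, PopulationMap

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_panel",
    "simulate_pedigree_phenotypes",
    "write_simulation",
]

GROUP_NAMES = ("source", "control", "recipient")


@dataclass
class SimConfig:
    """Three-population simulation parameters.

    ``tracts`` is a list of ``(chrom, start, end, carrier_fraction)`` with
    half-open bp coordinates; ``divergence`` acts as a drift (F-like)
    parameter between the source and control frequency profiles;
    ``recomb_shuffle`` is the expected crossover count per Mb when building
    recipient mosaics; ``tract_mut_rate`` mutates copied tracts so IBD
    detection must tolerate rare mismatches.
    """

    n_source: int = 50
    n_control: int = 50
    n_recipient: int = 40
    chrom_lengths: dict[str, int] = field(default_factory=lambda: {"1": 10_000_000})
    snp_density: float = 1.0  # SNPs per kb
    divergence: float = 0.2
    tracts: list[tuple[str, int, int, float]] = field(default_factory=list)
    recomb_shuffle: float = 5.0  # crossovers per Mb
    source_founders: int | None = None  # mosaic source pool from k founders
    source_recomb: float | None = None  # crossovers/Mb in the source pool
    tract_source_sweep: float = 0.0  # fraction of source pool fixed for the
    # tract haplotype (models a source-population sweep at the locus)
    tract_mut_rate: float = 0.001
    missing_rate: float = 0.0
    group_names: tuple[str, str, str] = GROUP_NAMES
    seed: int = 0

    def __post_init__(self) -> None:
        for n, what in ((self.n_source, "n_source"), (self.n_control, "n_control"),
                        (self.n_recipient, "n_recipient")):
            if n <= 0 or n % 2 != 0:
                raise ValueError(f"{what} must be a positive even haplotype count")
        if not 0.0 <= self.divergence <= 1.0:
            raise ValueError("divergence must be in [0, 1]")
        for chrom, start, end, frac in self.tracts:
            if chrom not in self.chrom_lengths:
                raise ValueError(f"tract chromosome {chrom!r} not simulated")
            if not (1 <= start < end <= self.chrom_lengths[chrom] + 1):
                raise ValueError(
                    f"tract {chrom}:{start}-{end} outside chromosome bounds"
                )
            if not 0.0 <= frac <= 1.0:
                raise ValueError("carrier_fraction must be in [0, 1]")


@dataclass
class SimTruth:
    """Ground truth emitted alongside a simulated panel."""

    tracts_by_hap: dict[str, list[tuple[str, int, int, str]]]
    source_freqs: np.ndarray
    control_freqs: np.ndarray
    config: SimConfig

    def carriers(self, chrom: str, start: int, end: int) -> list[str]:
        """Recipient haplotype ids carrying the given planted tract."""
        out = []
        for hap, tr in self.tracts_by_hap.items():
            if any(c == chrom and s == start and e == end for c, s, e, _ in tr):
                out.append(hap)
        return out


def _draw_positions(rng: np.random.Generator, length: int, density: float) -> np.ndarray:
    n = int(round(length / 1000.0 * density))
    n = min(n, length)
    pos = rng.choice(length, size=n, replace=False) + 1
    pos.sort()
    return pos.astype(np.int64)


def _diverged_freqs(rng: np.random.Generator, p: np.ndarray, f: float) -> np.ndarray:
    # Balding-Nichols style drift around the control profile
    if f <= 0:
        return p.copy()
    scale = (1.0 - f) / f
    a = np.maximum(p * scale, 1e-3)
    b = np.maximum((1.0 - p) * scale, 1e-3)
    return rng.beta(a, b)


def _mosaic(
    rng: np.random.Generator,
    pool: np.ndarray,
    n_out: int,
    pos: np.ndarray,
    length: int,
    xo_per_mb: float,
) -> np.ndarray:
    """Haplotypes assembled as crossover mosaics of ``pool`` rows."""
    m = pool.shape[1]
    out = np.empty((n_out, m), dtype=np.int8)
    mean_xo = xo_per_mb * length / 1e6
    for h in range(n_out):
        n_xo = rng.poisson(mean_xo)
        cuts = np.sort(rng.integers(1, length + 1, size=n_xo))
        bounds = np.concatenate(([0], np.searchsorted(pos, cuts), [m]))
        for b in range(len(bounds) - 1):
            lo, hi = bounds[b], bounds[b + 1]
            if hi > lo:
                out[h, lo:hi] = pool[rng.integers(pool.shape[0]), lo:hi]
    return out


def simulate_panel(cfg: SimConfig) -> tuple[HaplotypePanel, PopulationMap, SimTruth]:
    """Generate (panel, population map, truth) for a three-population scan.

    Deterministic given ``cfg`` (including its seed).
    """
    rng = np.random.default_rng(cfg.seed)
    src_name, ctl_name, rcp_name = cfg.group_names

    chroms_meta: list[tuple[str, np.ndarray]] = []
    for chrom, length in cfg.chrom_lengths.items():
        chroms_meta.append((chrom, _draw_positions(rng, int(length), cfg.snp_density)))

    n_src, n_ctl, n_rcp = cfg.n_source, cfg.n_control, cfg.n_recipient
    hap_names = (
        [f"SRC{i // 2 + 1}_{i % 2 + 1}" for i in range(n_src)]
        + [f"CTL{i // 2 + 1}_{i % 2 + 1}" for i in range(n_ctl)]
        + [f"RCP{i // 2 + 1}_{i % 2 + 1}" for i in range(n_rcp)]
    )
    rcp_hap_names = hap_names[n_src + n_ctl:]
    src_hap_names = hap_names[:n_src]

    all_chrom, all_pos, blocks = [], [], []
    p_src_all, p_ctl_all = [], []
    tracts_by_hap: dict[str, list[tuple[str, int, int, str]]] = {
        h: [] for h in rcp_hap_names
    }

    for chrom, pos in chroms_meta:
        m = len(pos)
        length = cfg.chrom_lengths[chrom]
        p_ctl = rng.uniform(0.05, 0.95, size=m)
        p_src = _diverged_freqs(rng, p_ctl, cfg.divergence)

        if cfg.source_founders:
            founders = (rng.random((cfg.source_founders, m)) < p_src).astype(np.int8)
            src_xo = (cfg.source_recomb if cfg.source_recomb is not None
                      else cfg.recomb_shuffle)
            src = _mosaic(rng, founders, n_src, pos, length, src_xo)
        else:
            src = (rng.random((n_src, m)) < p_src).astype(np.int8)
        ctl = (rng.random((n_ctl, m)) < p_ctl).astype(np.int8)

        # recipient mosaics of control haplotypes
        rcp = _mosaic(rng, ctl, n_rcp, pos, length, cfg.recomb_shuffle)

        # plant introgressed tracts
        for t_chrom, t_start, t_end, frac in cfg.tracts:
            if t_chrom != chrom:
                continue
            lo = int(np.searchsorted(pos, t_start, side="left"))
            hi = int(np.searchsorted(pos, t_end - 1, side="right"))
            if cfg.tract_source_sweep > 0 and hi > lo:
                # sweep the tract haplotype through the source pool: the
                # introgressed segment is the source major haplotype
                cons = (src[:, lo:hi].mean(axis=0) > 0.5).astype(np.int8)
                n_swept = int(round(cfg.tract_source_sweep * n_src))
                swept = rng.choice(n_src, size=n_swept, replace=False)
                src[np.ix_(swept, np.arange(lo, hi))] = cons[None, :]
            n_carriers = int(round(frac * n_rcp))
            carriers = rng.choice(n_rcp, size=n_carriers, replace=False)
            for h in carriers:
                donor = int(rng.integers(n_src))
                seg = src[donor, lo:hi].copy()
                if cfg.tract_mut_rate > 0 and hi > lo:
                    flips = rng.random(hi - lo) < cfg.tract_mut_rate
                    seg[flips] = 1 - seg[flips]
                rcp[h, lo:hi] = seg
                tracts_by_hap[rcp_hap_names[h]].append(
                    (chrom, t_start, t_end, src_hap_names[donor])
                )

        block = np.vstack([src, ctl, rcp])
        if cfg.missing_rate > 0:
            drop = rng.random(block.shape) < cfg.missing_rate
            block[drop] = MISSING
        blocks.append(block)
        all_chrom.append(np.full(m, chrom, dtype=object))
        all_pos.append(pos)
        p_src_all.append(p_src)
        p_ctl_all.append(p_ctl)

    alleles = np.hstack(blocks)
    chrom_arr = np.concatenate(all_chrom)
    pos_arr = np.concatenate(all_pos)
    sample_ids = (
        [f"SRC{i + 1}" for i in range(n_src // 2)]
        + [f"CTL{i + 1}" for i in range(n_ctl // 2)]
        + [f"RCP{i + 1}" for i in range(n_rcp // 2)]
    )
    popmap = PopulationMap(
        {s: src_name for s in sample_ids[: n_src // 2]}
        | {s: ctl_name for s in sample_ids[n_src // 2: (n_src + n_ctl) // 2]}
        | {s: rcp_name for s in sample_ids[(n_src + n_ctl) // 2:]}
    )
    variant_ids = [f"{c}:{p}" for c, p in zip(chrom_arr, pos_arr)]
    panel = HaplotypePanel(
        chrom=chrom_arr, pos=pos_arr, alleles=alleles,
        sample_ids=sample_ids, variant_ids=variant_ids,
    )
    truth = SimTruth(
        tracts_by_hap=tracts_by_hap,
        source_freqs=np.concatenate(p_src_all),
        control_freqs=np.concatenate(p_ctl_all),
        config=cfg,
    )
    return panel, popmap, truth


# ---------------------------------------------------------------------------
# pedigreed sow phenotypes

PARITY_EFFECTS = np.array([0.0, 0.35, 0.5, 0.4, 0.2, 0.0])
YEARSEASON_EFFECTS = np.array([0.0, 0.25, -0.25, 0.1])


def simulate_pedigree_phenotypes(
    n_sows: int,
    parities_per_sow: int = 3,
    h2: float = 0.3,
    pe_frac: float = 0.2,
    boar_frac: float = 0.05,
    q_effect: float = 0.0,
    q_freq: float = 0.5,
    seed: int = 0,
    mean_tnb: float = 12.0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series, pd.DataFrame]:
    """Simulate a sow pedigree with repeated litter-size records.

    The random part of each record has unit variance split as
    ``h2`` additive + ``pe_frac`` permanent environment + ``boar_frac``
    mating-boar + residual.  Breeding values transmit by parent average
    plus Mendelian sampling.  ``q_effect`` is added per copy of the Q
    allele (frequency ``q_freq``) carried by the sow.

    Returns ``(pedigree, phenotypes, true_bv, q_genotypes)`` where the
    pedigree has columns ``id sire dam`` ("0" = unknown), phenotypes has
    ``sow parity yearseason boar tnb`` and q_genotypes has
    ``sow q_count genotype``.
    """
    if not (h2 >= 0 and pe_frac >= 0 and boar_frac >= 0):
        raise ValueError("variance fractions must be nonnegative")
    if h2 + pe_frac + boar_frac >= 1.0:
        raise ValueError("h2 + pe_frac + boar_frac must be < 1")
    rng = np.random.default_rng(seed)

    n_fs = max(2, n_sows // 10)       # founder sires
    n_fd = max(2, n_sows // 2)        # founder dams
    n_boars = max(3, n_sows // 20)    # mating boars (pedigreed, non-founder)

    ids = [f"FS{i+1}" for i in range(n_fs)] + [f"FD{i+1}" for i in range(n_fd)]
    sires = ["0"] * (n_fs + n_fd)
    dams = ["0"] * (n_fs + n_fd)
    for i in range(n_boars):
        ids.append(f"B{i+1}")
        sires.append(f"FS{rng.integers(n_fs) + 1}")
        dams.append(f"FD{rng.integers(n_fd) + 1}")
    for i in range(n_sows):
        ids.append(f"S{i+1}")
        sires.append(f"FS{rng.integers(n_fs) + 1}")
        dams.append(f"FD{rng.integers(n_fd) + 1}")
    ped = pd.DataFrame({"id": ids, "sire": sires, "dam": dams})

    sigma_u = np.sqrt(h2)
    sigma_m = np.sqrt(boar_frac)
    sigma_p = np.sqrt(pe_frac)
    sigma_e = np.sqrt(1.0 - h2 - pe_frac - boar_frac)

    def transmit(sd: float) -> dict[str, float]:
        vals: dict[str, float] = {}
        for iid, s, d in zip(ped["id"], ped["sire"], ped["dam"]):
            if s == "0" and d == "0":
                vals[iid] = rng.normal(0.0, sd)
            else:
                pa = 0.5 * (vals.get(s, 0.0) + vals.get(d, 0.0))
                vals[iid] = pa + rng.normal(0.0, np.sqrt(0.5) * sd)
        return vals

    bv = transmit(sigma_u)
    boar_eff = transmit(sigma_m) if boar_frac > 0 else {i: 0.0 for i in ids}

    sow_ids = [f"S{i+1}" for i in range(n_sows)]
    boar_ids = [f"B{i+1}" for i in range(n_boars)]
    q_count = rng.binomial(2, q_freq, size=n_sows)
    pe = rng.normal(0.0, sigma_p, size=n_sows)

    rec = []
    for i, sow in enumerate(sow_ids):
        for parity in range(1, parities_per_sow + 1):
            ys = int(rng.integers(4))
            boar = boar_ids[int(rng.integers(n_boars))]
            y = (
                mean_tnb
                + PARITY_EFFECTS[min(parity - 1, len(PARITY_EFFECTS) - 1)]
                + YEARSEASON_EFFECTS[ys]
                + boar_eff[boar]
                + pe[i]
                + bv[sow]
                + q_effect * q_count[i]
                + rng.normal(0.0, sigma_e)
            )
            rec.append((sow, parity, f"ys{ys + 1}", boar, y))
    phen = pd.DataFrame(rec, columns=["sow", "parity", "yearseason", "boar", "tnb"])

    true_bv = pd.Series({i: bv[i] for i in ids}, name="true_bv")
    labels = np.array(["qq", "Qq", "QQ"])[q_count]
    q_geno = pd.DataFrame({"sow": sow_ids, "q_count": q_count, "genotype": labels})
    return ped, phen, true_bv, q_geno


def write_simulation(
    out_dir: str | Path,
    panel: HaplotypePanel,
    popmap: PopulationMap,
    truth: SimTruth,
) -> None:
    """Write panel VCF, population map TSV and truth JSON into ``out_dir``."""
    from .genotype_io import write_vcf

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_vcf(panel, out / "panel.vcf")
    popmap.to_tsv(out / "pops.tsv")
    cfg = asdict(truth.config)
    cfg["tracts"] = [list(t) for t in cfg["tracts"]]
    payload = {
        "config": cfg,
        "tracts_by_hap": {
            h: [list(t) for t in tr] for h, tr in truth.tracts_by_hap.items() if tr
        },
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(payload, fh, indent=1)
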