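"""End-to-end orchestration of the introgression scan workflow."""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .association import anova_oneway
from .ebv_blup import Pedigree, VarianceComponents, solve_mme
from .genotype_io import (HaplotypePanel, PopulationMap, VariantFilterConfig,
                          filter_variants, load_phased_vcf, make_windows)
from .haplotype_analysis import (build_haplotype_set, call_Qq, informative_snps,
                                 major_haplotype, tag_snps)
from .ibd_scan import ibd_sharing_table
from .region_call import (genome_fraction, merge_regions, quantile_threshold,
                          regions_to_bed, regions_to_frame)
from .synthetic_data import (SimConfig, simulate_panel,
                             simulate_pedigree_phenotypes, write_simulation)

logger = logging.getLogger("introscan")

__all__ = ["RunConfig", "run_full_scan"]


@dataclass
class RunConfig:
    """Parameters of the full scan; defaults follow the published workflow."""

    out_dir: str = "introscan_run"
    vcf: str | None = None          # None -> simulate a preset dataset
    pops: str | None = None
    recipient: str = "recipient"
    source: str = "source"
    control: str = "control"
    bin_size: int = 10_000
    top_fraction: float = 0.005
    merge_gap_bp: int = 200_000
    min_seg_kb: float = 150.0
    min_seg_snps: int = 100
    max_mismatch_rate: float = 0.02
    maf_min: float = 0.05
    max_missing: float = 0.1
    min_abs_diff: float = 0.8
    n_tags: int = 2
    n_sows: int = 300
    q_effect: float = 0.5
    seed: int = 1
    chrom_lengths: dict[str, int] | None = None
    sim_config: SimConfig | None = None  # overrides the default preset

    def validate(self) -> None:
        for name in ("bin_size", "merge_gap_bp", "min_seg_snps", "n_tags", "n_sows"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.top_fraction < 1:
            raise ValueError("top_fraction must be in (0, 1)")


def _default_sim_config(cfg: RunConfig) -> SimConfig:
    return SimConfig(
        n_source=50, n_control=50, n_recipient=40,
        chrom_lengths={"1": 10_000_000, "2": 10_000_000},
        snp_density=1.0,
        divergence=0.2,
        tract_source_sweep=1.0,
        recomb_shuffle=50.0,
        tracts=[("1", 3_000_001, 3_400_001, 0.6),
                ("1", 7_500_001, 8_000_001, 0.6),
                ("2", 5_000_001, 5_300_001, 0.6)],
        seed=cfg.seed,
    )


def run_full_scan(cfg: RunConfig) -> dict:
    """Run simulate/load -> filter -> rIBD -> regions -> haplotypes ->
    Q/q calls -> BLUP EBVs -> association, writing all artifacts.

    Deterministic given (inputs, config, seed).  Returns a summary dict of
    the key results (also written to ``summary.json``).
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    t0 = time.time()

    try:
        with open(out / "config.json", "w") as fh:
            json.dump(dataclasses.asdict(cfg) | {"version": __version__}, fh, indent=1)

        # --- stage: inputs ----------------------------------------------
        if cfg.vcf is None:
            sim_cfg = cfg.sim_config or _default_sim_config(cfg)
            panel, popmap, truth = simulate_panel(sim_cfg)
            write_simulation(out / "sim", panel, popmap, truth)
            chrom_lengths = sim_cfg.chrom_lengths
            logger.info("simulated panel: %d samples x %d variants",
                        panel.n_samples, panel.n_variants)
        else:
            if cfg.pops is None:
                raise ValueError("--pops is required when --vcf is given")
            panel = load_phased_vcf(cfg.vcf)
            popmap = PopulationMap.from_tsv(cfg.pops)
            chrom_lengths = cfg.chrom_lengths or {
                c: int(panel.pos[panel.chrom == c].max())
                for c in panel.chromosomes()
            }
            logger.info("loaded %s: %d samples x %d variants",
                        cfg.vcf, panel.n_samples, panel.n_variants)
        popmap.validate_panel(panel)
        for role, grp in (("recipient", cfg.recipient), ("source", cfg.source),
                          ("control", cfg.control)):
            if grp not in popmap.groups():
                raise ValueError(f"{role} group {grp!r} absent from population map")

        # --- stage: variant filter --------------------------------------
        panel, fstats = filter_variants(
            panel, VariantFilterConfig(cfg.maf_min, cfg.max_missing),
            with_stats=True,
        )
        logger.info("variant filter: %s", fstats)

        # --- stage: rIBD scan -------------------------------------------
        table = ibd_sharing_table(
            panel, popmap, cfg.recipient, cfg.source, cfg.control,
            bin_size=cfg.bin_size, min_kb=cfg.min_seg_kb,
            min_snps=cfg.min_seg_snps, max_mismatch_rate=cfg.max_mismatch_rate,
            chrom_lengths=chrom_lengths,
        )
        table.to_csv(out / "ribd_windows.tsv", sep="\t", index=False,
                     float_format="%.6g")
        logger.info("rIBD scan: %d bins, mean rIBD %.4f",
                    len(table), table["rIBD"].mean())

        # --- stage: region calling --------------------------------------
        windows = make_windows(panel, cfg.bin_size, min_snps=1,
                               chrom_lengths=chrom_lengths)
        thr, flags = quantile_threshold(windows, table["rIBD"].to_numpy(),
                                        cfg.top_fraction)
        regions = merge_regions(windows, flags, cfg.merge_gap_bp,
                                table["rIBD"].to_numpy())
        regions_to_frame(regions).to_csv(out / "regions.tsv", sep="\t", index=False,
                                         float_format="%.6g")
        regions_to_bed(regions, out / "regions.bed")
        frac = genome_fraction(regions, chrom_lengths)
        logger.info("regions: %d called, threshold %.4f, genome fraction %.4f",
                    len(regions), thr, frac)

        # --- stage: haplotype analysis on the top region ----------------
        summary: dict = {
            "n_variants": panel.n_variants,
            "ribd_threshold": thr,
            "n_regions": len(regions),
            "genome_fraction": frac,
            "mean_ribd": float(table["rIBD"].mean()),
        }
        if regions:
            top = max(regions, key=lambda r: r.peak_stat)
            summary["top_region"] = [top.chrom, top.start, top.end]
            region_panel = panel.restrict(top.chrom, top.start, top.end)
            local_info = informative_snps(region_panel, popmap, cfg.recipient,
                                          cfg.control, cfg.min_abs_diff)
            snps = local_info if local_info.size else None
            hset = build_haplotype_set(region_panel, popmap, snps=snps)
            hap_rows = [
                (lab, hset.allele_string(lab), int(hset.total_counts[k]),
                 *[int(hset.group_counts.loc[lab, g])
                   for g in hset.group_counts.columns])
                for k, lab in enumerate(hset.labels)
            ]
            pd.DataFrame(
                hap_rows,
                columns=["hap", "alleles", "total",
                         *hset.group_counts.columns],
            ).to_csv(out / "haplotypes.tsv", sep="\t", index=False)
            logger.info("top region %s:%d-%d: %d haplotypes (%d informative SNPs)",
                        top.chrom, top.start, top.end, hset.n_haplotypes,
                        0 if snps is None else len(snps))

            q_major = major_haplotype(hset, cfg.source)
            try:
                tags = tag_snps(hset, {q_major}, n_tags=cfg.n_tags, seed=cfg.seed)
                pattern = hset.alleles[hset.labels.index(q_major), tags]
                tag_panel_idx = hset.variant_idx[tags]
                calls = call_Qq(region_panel, tag_panel_idx, pattern)
                calls.to_csv(out / "qq_calls.tsv", sep="\t", index=False)
                summary["q_haplotype"] = q_major
            except Exception as exc:
                logger.warning("tag-SNP stage skipped: %s", exc)
                calls = None
        else:
            calls = None

        # --- stage: pedigree BLUP + association -------------------------
        ped_df, phen, true_bv, q_geno = simulate_pedigree_phenotypes(
            n_sows=cfg.n_sows, q_effect=cfg.q_effect, seed=cfg.seed,
        )
        ped_df.to_csv(out / "pedigree.tsv", sep="\t", index=False)
        phen.to_csv(out / "phenotypes.tsv", sep="\t", index=False,
                    float_format="%.6g")
        ped = Pedigree(ped_df)
        vc = VarianceComponents(sigma_u2=0.3, sigma_m2=0.05, sigma_p2=0.2,
                                sigma_e2=0.45)
        sol = solve_mme(phen, ped, vc)
        sol.ebv.rename_axis("id").reset_index().to_csv(
            out / "ebv.tsv", sep="\t", index=False, float_format="%.6g")

        sows = q_geno["sow"].tolist()
        res = anova_oneway(sol.ebv.loc[sows].to_numpy(),
                           q_geno["genotype"].to_numpy())
        res.summary().to_csv(out / "assoc.tsv", sep="\t", index=False,
                             float_format="%.6g")
        summary["anova_p"] = res.p
        summary["anova_f"] = res.f
        logger.info("association: F=%.3f p=%.3g", res.f, res.p)

        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=1)
        logger.info("done in %.1fs", time.time() - t0)
        return summary
    finally:
        logger.removeHandler(handler)
        handler.close()
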