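# introscan

Genome scans for adaptive introgression between pig populations, and the
downstream quantitative-genetics analysis linking an introgressed haplotype
to litter-size breeding values. The package implements, as reusable tested
components:

- **genotype_io** — phased-VCF ingestion into a haplotype panel, the
  site QC filters (MAF > 0.05, missing rate < 0.1, biallelic only), and
  genome-window tiling shared by all scans.
- **synthetic_data** — a three-population simulator (source / control /
  recipient) with planted introgressed tracts and full ground-truth
  bookkeeping, plus a pedigreed-sow phenotype simulator with a known
  haplotype effect.
- **popstruct** — group allele frequencies, p-distance matrices,
  neighbor-joining trees (Saitou–Nei), and PLINK-style variance-standardized
  PCA.
- **ibd_scan** — deterministic seed-and-extend IBD segment detection on
  phased haplotypes and the per-10 kb-bin sharing statistics
  nIBD = cIBD/tIBD and rIBD = nIBD_source − nIBD_control.
- **selection_scan** — windowed Hudson Fst, locus-specific branch lengths
  (LSBL), expected heterozygosity 2p(1−p) with genome-wide Z-standardization
  (Zhet), and one-sided Z-test significance masks.
- **region_call** — top-quantile thresholding (default top 0.5%), merging of
  flagged windows closer than 200 kb, and genome-fraction bookkeeping.
- **haplotype_analysis** — informative-SNP filtering (|Δp| > 0.8), regional
  haplotype frequency tables, major/minor heat-map recoding, minimum-spanning
  haplotype networks, tag-SNP selection and Q/q genotype calling.
- **ebv_blup** — pedigree numerator relationship matrix (tabular method and
  direct sparse inverse), and Henderson's mixed-model equations for the
  repeated-records animal model (parity + year-season fixed effects;
  additive, mating-boar and permanent-environment random effects).
- **association** — one-way ANOVA of EBVs across Q/q genotype classes, plus
  FPKM transformation and per-gene two-sample t-tests for expression
  comparisons.

## CLI

All stages are exposed through a single `introscan` entry point:

```sh
# synthetic data with ground truth
introscan simulate --preset introgression --seed 1 --out sim/
introscan simulate --preset pedigree --seed 1 --out ped/

# individual stages
introscan filter --vcf sim/panel.vcf --maf 0.05 --max-missing 0.1 --out filtered.vcf
introscan popstruct --vcf sim/panel.vcf --pops sim/pops.tsv --tree out.nwk --pca pca.tsv
introscan ribd --vcf sim/panel.vcf --pops sim/pops.tsv \
    --recipient recipient --source source --control control --out ribd.tsv
introscan sweep --vcf sim/panel.vcf --pops sim/pops.tsv \
    --group-a recipient --group-b control --out sweep.tsv
introscan regions --windows ribd.tsv --stat rIBD --top 0.005 \
    --merge-gap 200000 --out regions.tsv
introscan haplotypes --vcf sim/panel.vcf --pops sim/pops.tsv \
    --region 1:3000001-3400000 --ref-group recipient --q-from source \
    --out-dir haps/
introscan ebv --ped ped/pedigree.tsv --phen ped/phenotypes.tsv --out ebv.tsv
introscan assoc --ebv ebv.tsv --qq calls.tsv --out assoc.tsv

# everything end-to-end (simulated preset when no --vcf is given)
introscan all --out run/ --seed 1
```

Every command is deterministic given its inputs and `--seed`; `introscan all`
echoes the effective configuration and a stage log into the run directory.

## Conventions

Positions are 1-based inclusive in VCF I/O; windows and regions are half-open
`[start, end)` internally; BED exports are 0-based half-open. Missing alleles
are excluded from every allele-frequency denominator. The allele matrix holds
phased haplotypes as rows (two per sample) coded 0/1 with −1 for missing.
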