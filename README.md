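# herdscan

A tested, reusable pipeline for SNP-array population genetics in livestock:
genotype QC, population-structure statistics, runs-of-homozygosity (ROH)
detection, genomic and pedigree inbreeding, and a windowed d_i
selection-signature scan — plus a synthetic-data module that generates
multi-population panels and pedigrees with exactly known truth (allele
frequencies, divergence, autozygous tracts) so every stage can be validated
against ground truth.

## Modules

| Module | What it does |
| --- | --- |
| `herdscan.genotype_io` | PLINK-text PED/MAP reading/writing, panel intersection, call-rate filter, exact Hardy–Weinberg test, per-population MAF/HWE QC |
| `herdscan.synthetic_data` | Balding–Nichols population frequencies, pedigree gene-dropping with Haldane recombination and exact autozygous-tract truth, population crosses |
| `herdscan.structure` | Observed heterozygosity, 1−IBS distances, method-of-moments IBD sharing (PI_HAT), classical (Torgerson) MDS, Weir–Cockerham pairwise F_ST with percentile-bootstrap CIs, Saitou–Nei neighbor joining |
| `herdscan.roh_inbreeding` | Exact maximal-run ROH detection, F_ROH / F_HOM / F_PED / PCI_5G, ROH summaries, per-SNP ROH incidence, inbreeding comparisons |
| `herdscan.selection_scan` | Per-SNP pairwise Weir–Cockerham F_ST, standardized d_i, 1-Mb window averaging, nearest-rank 99th-percentile calling, private/shared window classification |
| `herdscan.cli_pipeline` | `herdscan` CLI and the stage orchestrator with deterministic seeding and a run manifest |
| `herdscan.pedigree` | Pedigree graph, recursive kinship, Wright's inbreeding, pedigree completeness |

## CLI

```sh
# generate a synthetic panel with truth files
herdscan simulate --config sim.yaml --seed 1 --out out/

# QC with the standard thresholds
herdscan qc --ped out/sim.ped --map out/sim.map --pops out/populations.tsv \
    --geno 0.1 --maf 0.01 --hwe 0.0001 --out qc/

# structure, ROH, inbreeding, scan
herdscan structure --ped ... --map ... --pops ... --mds-dims 2 --boot 1000 --seed 1 --out st/
herdscan roh --ped ... --map ... --pops ... --homozyg-snp 50 --homozyg-kb 1000 \
    --homozyg-density 100 --homozyg-gap 1800 --homozyg-het 0 --homozyg-missing 2 --out roh/
herdscan inbreed --ped ... --map ... --pops ... --pedigree ped.tsv --out inb/
herdscan scan --ped ... --map ... --pops ... --window-mb 1 --min-snps 4 --percentile 99 --out scan/

# everything from one config
herdscan all --config pipeline.yaml --seed 1 --out run/
```

All outputs are TSV (Newick for trees) plus a `manifest.json` recording input
checksums, parameters, derived stage seeds and output row counts; identical
config + seed reproduces byte-identical outputs.

An example `all` config:

```yaml
seed: 1
simulate:
  n_chromosomes: 29
  chrom_length_bp: 100000000
  n_snps_per_chrom: 1100
  populations:
    - [A, 0.05, 30]
    - [B, 0.10, 30]
  crosses:
    - [X, A, B, 0.2]
  pedigree_depth: 3
  mating_scheme: full_sib_loop
qc: {geno: 0.1, maf: 0.01, hwe: 0.0001}
roh: {homozyg_snp: 50, homozyg_kb: 1000, homozyg_density: 100, homozyg_gap: 1800}
scan: {window_mb: 1, min_snps: 4, percentile: 99}
```

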