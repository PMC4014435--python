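# paleogen

Ancient-DNA population genetics toolkit: pseudo-haploid calling and damage
handling, panel merging, D/f3 statistics with weighted block jackknife,
derived-allele sharing, admixture-model fitting and projection, PCA
projection of low-coverage samples, and coalescent divergence-time
estimation — validated end-to-end on synthetic data with known truth.

## Modules

| module | contents |
| --- | --- |
| `paleogen.datamodel_io` | `SNPRecord`/`GenotypePanel`/`FrequencyPanel` types; EIGENSTRAT (.geno/.snp/.ind), VCF (bi-allelic SNPs), frequency-table TSV, BED masks, samtools-style text pileups; 5 Mb jackknife block assignment |
| `paleogen.synthetic_data` | demography graphs (drift + admixture edges), Balding–Nichols frequency simulation, genotype sampling, ancient-sample degradation (C>T/G>A damage, missingness), pileup simulation, Monte Carlo trio-genealogy oracle |
| `paleogen.ancient_calling` | BQ/MQ read filters, pseudo-haploid calling (uniform over retained reads), diploid variant filter predicate (QUAL > 40, depth ∈ [6, 30], gap ≥ 5, repeats), damage flagging |
| `paleogen.panel_merge` | merge ancient calls into panels with mismatch accounting, damage/transition exclusion, haploidization, ancestry-tract masking, missingness/ascertainment filters, polarization |
| `paleogen.fstats` | D-statistics, f3 (optional finite-sample correction), derived-allele sharing, weighted block jackknife |
| `paleogen.ancestry_models` | binomial-likelihood admixture EM (fit + fixed-P projection), cluster alignment, RMSE subset evaluation, PCA with least-squares projection |
| `paleogen.divergence` | concordant/discordant topology counts, virtual haploid genomes, closed-form discordance curve, τ estimation with jackknife CI, year conversion |
| `paleogen.cli` | `paleogen` command with all subcommands |

## CLI

All subcommands write TSVs with `#`-prefixed metadata headers (version,
seed, parameters; no timestamps) so seeded runs are byte-reproducible.
Exit codes: 0 success, 1 data error, 2 usage error.

```sh
# simulate a panel + ancient sample from a declarative YAML demography
paleogen simulate --config demog.yaml --out-prefix out/sim

# pseudo-haploid calling from a text pileup
paleogen call --pileup out/sim.X0.pileup --sample X0 --seed 7 --out out/X0.tsv

# merge into the modern panel, drop damage sites, polarize
paleogen merge --panel out/sim --calls out/X0.tsv --out-prefix out/merged --polarize

# statistics
paleogen dstat --freqs out/sim.freq.tsv --o O --x X --p1 A --p2 B --out out/d.tsv
paleogen f3 --freqs out/sim.freq.tsv --c X --a A --b B --no-corrected --out out/f3.tsv
paleogen share --panel out/merged --ancient X0 --out out/share.tsv

# admixture model: fit moderns, project the ancient sample, evaluate subsets
paleogen admix-fit --panel out/sim --k 2 --seed 1 --out-prefix out/adm
paleogen admix-project --panel out/merged --sample X0 --p-matrix out/adm.P.tsv --out out/q.tsv
paleogen admix-rmse --panel out/merged --k 2 3 --ancient X0 --out out/rmse.tsv

# PCA projection and divergence time
paleogen pca-project --panel out/merged --project X0 --out out/pca.tsv
paleogen divergence --freqs out/sim.freq.tsv --calls out/X0.tsv \
    --population A --ne-label Europe --out out/div.tsv
```

A demography config looks like:

```yaml
seed: 7
sites: 5000
genome: {"1": 100000000, "2": 100000000}
damage_rate: 0.2
missing_rate: 0.5
pileup: {mean_depth: 3.0, base_error: 0.01}
root: {name: R, freq: [0.05, 0.95]}
edges:
  - {child: A, parent: R, F: 0.1}
  - {child: B, parent: R, F: 0.1}
admixtures:
  - {child: X, parents: [A, B], alpha: 0.5}
samples:
  - {population: A, n: 10}
  - {population: B, n: 10}
  - {population: X, n: 1, ploidy: 1, class: ancient}
```

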