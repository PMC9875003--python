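# breedopt

Budget-constrained breeding-scheme simulation and Bayesian optimisation
of breeding-scheme decision variables.

A breeding campaign is described by fixed constraints — total budget
`B`, phenotyping cost per plot `C_p`, cost per new genotyped individual
`C_n`, number of selection cycles `n_gen`, and a founder population —
and four decision variables: the initial and later selection intensities
(`i_init`, `i`), the budget fraction spent on new individuals (`b_rep`),
and the phenotyping period (`pheno_p`). The simulator runs the full
phenotype → ridge-predict → select → TSP-mate → cross loop (Poisson
crossover meiosis on a Morgan-scaled genetic map) and returns the mean
true genotypic value of the final generation. A Gaussian-process
Bayesian optimiser (expected improvement, constant-liar batching, focus
search) tunes the four decision variables against that objective, with a
random-search baseline and pairwise-comparison reporting.

## Layout

| module | contents |
| --- | --- |
| `breedopt.genome` | genetic map, haplotypes, populations; VCF/CSV founder I/O; synthetic homozygous founders |
| `breedopt.trait` | QTN effect sampling, heritability calibration, plot phenotypes |
| `breedopt.meiosis` | crossover sampling, gametes (single and vectorised batch), crossing |
| `breedopt.scheme` | resource derivation from budget, ridge genomic prediction, mating order, the breeding loop |
| `breedopt.bayesopt` | search space, Latin hypercube, GP fit/posterior, EI, constant liar, focus search, optimisation loops |
| `breedopt.evaluate` | the eight constraint scenarios, win proportions, ECDFs, representative runs, full experiments |
| `breedopt.cli` | `breedopt` command-line interface |

## CLI

```bash
# synthetic homozygous founders (CSV dosage matrix + map + chromosome table)
breedopt simulate-founders --n-ind 198 --n-chr 20 --n-snp 3000 --seed 1 --out-prefix founders

# one breeding campaign under scenario e (H2=0.7, n_gen=5, B=1000)
breedopt run-scheme --scenario e --i-init 0.2 --i 0.1 --b-rep 0.5 --pheno-p 1 --seed 1

# optimise the four decision variables
breedopt optimize --method bayes --scenario e --n-iter 15 --q 2 --seed 1 --out run.json

# repeat campaigns at a fixed parameter set
breedopt evaluate --scenario e --params 0.2 0.1 0.5 1 --n-evaluation 32 --seed 1

# full Bayesian-vs-random comparison batch from a YAML config
breedopt compare --config batch.yaml --out report.json
```

A `compare` config mirrors `breedopt.evaluate.ExperimentConfig`:

```yaml
scenarios: [e]
n_runs: 20
n_iter: 10
q: 2
n_evaluation: 1
comparison: all_runs   # or: representative
seed: 99
```

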