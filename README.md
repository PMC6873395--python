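# otusim

Simulator for sparse 16S rDNA-seq–style OTU count tables.

The generative model has two stages. Biological variability between
replicates of a group is drawn per feature from a gamma distribution with
mean `mu` and variance `phi * mu^2`. Sequencing is then modelled as drawing
the requested library size *without replacement* from the finite integer pool
of fragments of each replicate — an exact multivariate hypergeometric (MHG)
draw, implemented by sequential conditional univariate hypergeometric
sampling. Compositionality and zeros arise intrinsically: counts are
constrained to sum to the library size, and rare features are simply the ones
most likely never to be sampled at finite depth.

The package also ships:

* **estimation** — recover per-group `mu`, `phi` and library sizes from a
  real count table (total-sum or median-of-ratios normalization; Poisson-
  corrected or CV² moment estimators for `phi`; hybrid user/estimated
  assembly);
* **presets** — parameterized scenario families (uniform / geometric /
  lognormal abundance shapes, optional injected differential abundance)
  spanning realistic regimes: 2–40 groups, 2–5 replicates, depths from
  ~3·10³ to ~8·10⁵, sparsity up to ~97%;
* **evaluation** — the real-vs-simulated fidelity protocol: sparsity
  (total / per-row / per-column / per-group), group mean intensity,
  variance and relative variance, compared by two-sided Mann–Whitney U
  tests, rank-biserial effect sizes and a 10000-iteration bootstrap over 5%
  feature subsets;
* **io / CLI** — TSV/CSV (and MatrixMarket) readers with strict validation,
  versioned JSON parameter files, YAML scenario files, tidy TSV reports.

## CLI

```sh
# list scenario presets / inspect one
otusim presets
otusim presets hmp_like

# simulate from a preset (seed is mandatory)
otusim simulate --preset da_benchmark --seed 42 --out sim/

# estimate parameters from a real table, then simulate from them
otusim estimate --counts real_counts.tsv --metadata metadata.tsv --out params.json
otusim simulate --params params.json --seed 7 --out resim/

# compare a real and a simulated table
otusim evaluate --real real_counts.tsv --sim resim/counts.tsv \
    --metadata metadata.tsv --sim-metadata resim/metadata.tsv --out report/
```

Count tables are features × samples with a `feature_id` first column and
sample IDs in the header; metadata is a `sample_id` / `group` table. A
simulation writes `counts.tsv`, `relative_abundances.tsv` (the
pre-sequencing ground-truth composition, columns summing to 1),
`params.json`, `metadata.tsv` and a `manifest.json` with the seed that
reproduces the run bit-for-bit.

## Python API

```python
import otusim

scenario = otusim.get_preset("da_benchmark", seed=1)
params = otusim.expand_preset(scenario)
result = otusim.simulate(params, seed=1)           # counts + ground truth
est = otusim.estimate_parameters(result.to_table())
report = otusim.compare_tables(result.to_table(), otusim.simulate(est, seed=2).to_table())
```

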