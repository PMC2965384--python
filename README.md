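# arraycna

Allele-specific somatic copy number, LOH, tumor purity and ploidy inference
from SNP-genotyping-array data (Log R Ratio / B allele frequency), plus a
synthetic tumor-mixture simulator with known truth.

The model is a Bayesian hidden Markov model over 21 tumor states (joint copy
number and allowable constitutional/tumor genotype combinations). Emissions
are K-component mixtures of bivariate Student-t distributions around
mixed-genotype means, with a uniform outlier class, a GC-content regression on
the LRR, a genome-wide normal-DNA fraction `pi0`, per-locus intra-tumor
heterogeneity levels `pi_i`, and an LRR baseline adjustment `beta0` that
resolves the ploidy normalization ambiguity of array data. Transitions are
distance-dependent (`rho = (1 - exp(-d / 2L)) / 2`, `L` = 2 Mb by default).
Fitting is MAP-EM with conjugate priors, multiple baseline/purity restarts,
Viterbi segmentation and per-segment log Bayes factor scoring (default filter
threshold 30, natural log).

## Library quick start

```python
from arraycna import (SimConfig, simulate_sample, fit_with_restarts,
                      Hyperparams, segments_from_path)

probes, truth = simulate_sample(SimConfig(n_probes=20_000, pi0_true=0.5,
                                          seed=1))
fit = fit_with_restarts(probes, hyper=Hyperparams())
print(fit.pi0, fit.params.beta0)          # normal fraction, baseline shift
segments = segments_from_path(probes, fit.viterbi_path)
```

Key entry points:

* `arraycna.state_space.build_state_table()` — the 21-state model.
* `arraycna.emission` — emission parameters, means, Student-t densities.
* `arraycna.hmm` — `forward_backward`, `viterbi`, `em_fit`,
  `fit_with_restarts`, `likelihood_surface`.
* `arraycna.scoring` — segmentation, Bayes factors, chromosome-number and
  ploidy estimates, summary report.
* `arraycna.simulate` — `simulate_sample`, `dilution_series` (cell- or
  mass-fraction mixing), `make_confusable_sample`.
* `arraycna.io` — probe-table reader (BeadStudio-style TSV), GC track
  attachment, output writers.

## Command line

```bash
# simulate a 50:50 normal:tumor mixture
arraycna simulate --out demo --n-probes 20000 --pi0 0.5 --seed 1

# fit the full model and write call tables
arraycna run --input demo.probes.tsv --outdir results \
    --variant full --em-iters 15 --lbf-threshold 30 --seed 1

# export the tumor-state table
arraycna states
```

`run` writes `per_snp.tsv`, `segments.tsv`, `segments.bed`, `summary.tsv`
and `run_log.json` (seed, hyperparameters, restart table). `--variant`
selects the nested model variants (`germline`, `ploidy`, `normal`, `full`);
`--surface` additionally writes the (pi0, beta0) profile-likelihood TSV.
A YAML file passed via `--config` can override hyperparameters and the
initial emission parameters.

## Notes

* The GC covariate is centered internally, so `beta0` is the LRR baseline at
  average GC content.
* Probe tables are tab-delimited with columns Name / Chr / Position /
  Log R Ratio / B Allele Freq (case-insensitive aliases accepted); rows with
  non-finite values are dropped and duplicate positions deduplicated.
* Per-locus heterogeneity levels are supported through a discrete grid
  (`Hyperparams.pi_grid`); purity/ploidy restarts are selected under the
  heterogeneity-free restriction and then refined, which keeps the
  genome-doubled and contamination-shifted readings comparable.
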