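# grud

Missing-data-aware GRU classifiers for irregularly sampled multivariate time
series.

Clinical and sensor time series are rarely complete: variables are observed
at irregular, per-variable times, and *which* measurements are missing is
often itself predictive ("informative missingness"). This package implements
a GRU cell augmented with two trainable decay mechanisms driven by each
variable's time-since-last-observation:

- **input decay** pulls a stale last observation back toward the training
  mean (per-variable, diagonal weight), and
- **hidden decay** attenuates the previous hidden state through a dense map
  of the full interval vector,

with the observation mask additionally fed to every gate. Alongside it are
the three standard baselines (mean imputation, forward filling, and
concatenating values with masks and intervals), all trained with Adam,
recurrent dropout, batch-norm + dropout heads, early stopping on validation
AUC, and parameter-count parity across architectures.

There is no deep-learning framework dependency: the cells are plain NumPy,
with analytic gradients through the unrolled recurrence via
[autograd](https://github.com/HIPS/autograd), validated against central
finite differences.

## Layout

| module | contents |
| --- | --- |
| `grud.core` | data model: values/mask/stamps/intervals, empirical means, z-scoring |
| `grud.imputation` | mean / forward imputation, mask+interval concatenation |
| `grud.cell` | GRU and decay-augmented GRU steps, unrolling, parameter counting |
| `grud.training` | heads, losses, co-occurrence prior, Adam + early stopping, CV |
| `grud.synthetic` | generator with tunable label/missing-rate correlation |
| `grud.evaluation` | AUC, online (truncated-prefix) prediction curves, decay reports |
| `grud.io`, `grud.cli` | long-format CSV I/O and the `grud` command line |

## Command line

```sh
# a dataset whose missing rates correlate with the label (rho in [0, 1])
grud generate --out data.csv --labels labels.csv --report gen.json \
     --n 500 --d 10 --t 30 --rho 0.6 --seed 1

# fit one model (config is YAML of grud.training.ModelConfig fields)
grud train --data data.csv --labels labels.csv --config cfg.yaml \
     --mode grud --seed 1 --out model.json

# stratified 5-fold cross-validated AUC
grud evaluate --data data.csv --labels labels.csv --config cfg.yaml --folds 5

# AUC vs observation cutoff, using only data observed by each cutoff
grud online-curve --model model.json --data data.csv --labels labels.csv

# learned input-decay curves and hidden-decay weight magnitudes
grud decay-report --model model.json --out decay.json

# the full mode x informativeness comparison table
grud sweep --rho-grid 0,0.3,0.6,0.9 --n 500 --seeds 5 --out sweep.csv
```

Data interchange is a tidy long CSV (`sample_id,time,variable,value`, one
observed measurement per row) plus a `sample_id,label` CSV; model
checkpoints are JSON with arrays keyed by parameter symbol names.

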