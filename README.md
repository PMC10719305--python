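# aftmix

Sparse finite mixtures of accelerated failure time (AFT) regressions for
right-censored survival data with DNA-methylation covariates.

## The problem

In cancer cohorts, the effect of a gene's promoter methylation on overall
survival is often *heterogeneous*: a gene that shortens survival in one
subpopulation of patients may be irrelevant in another. A single AFT or Cox
regression averages these effects away. `aftmix` is built for analysts who
suspect such latent subpopulations — for example, colorectal-cancer cohorts
whose log survival-time density is visibly bimodal — and want to estimate,
per subpopulation, which genes matter and how strongly.

## The model

Log survival time `y = log t` follows, within latent component
`k = 1, …, K`,

```
y = β₀ₖ + x'βₖ + σₖ ε,    ε ~ N(0, 1),
```

where `x` holds log-transformed average promoter methylation. With
right-censoring indicator `δ` (1 = event observed), the observed-data
likelihood of subject `i` is

```
Σₖ πₖ fₖ(yᵢ)^δᵢ Sₖ(yᵢ)^(1−δᵢ),
```

with `fₖ`, `Sₖ` the normal density and survival function at the component's
linear predictor. Each `βₖ` is sparse; sparsity is imposed with per-component
SCAD penalties whose K tuning parameters are chosen by a data-adaptive
component-wise BIC, and the number of components by an overall BIC. Fitting
is an EM algorithm with truncated-normal imputation of censored outcomes and
penalized weighted least-squares M-steps; see `docs/methods.md` for the full
account.

The pipeline around the model: censoring-aware diagnostics (Kaplan–Meier,
IPC-weighted density of log survival, Gaussian-mixture BIC scan), screening
of candidate genes by correlation-adjusted survival scores (IPCW-weighted
marginal correlations decorrelated through `R^{−1/2}`), and a synthetic-data
generator with known ground truth so every stage is testable without any
external download.

## Worked example

Simulate a cohort mirroring the shipped two-component scenario (521
subjects, 99 genes, 46%/54% mixing, 50% censoring), then run the full
pipeline — diagnostics, screening, order selection, fit — from the shell:

```bash
aftmix simulate --seed 1 --out demo/sim
aftmix run --survival demo/sim/dataset.tsv --pre-transformed \
    --m 99 --krange 1:3 --seed 1 --out demo/run
```

which prints

```
simulated n=521, p=99, censored 49.1% -> demo/sim/dataset.tsv
pipeline complete: K=2, pi=[0.433, 0.567], active=[5, 4] -> demo/run
```

The pipeline selected a two-component mixture (`K=2`); about 43% of the
cohort belongs to Component 1, the aggressive short-survival group
(truth: 46%), and the components retain 5 and 4 active genes (truth: 5 per
component). `demo/run/coefficients.tsv` holds the per-gene effects in each
component, `posteriors.tsv` the per-subject membership probabilities with
vital status (ready for a posterior-probability plot separated by
alive/deceased), and `summary.json` the chosen K, BIC table, mixing
proportions and active-gene counts.

The same stages are available as a library:

```python
from aftmix import synthetic, select_order, classify

sim = synthetic.simulate_dataset(synthetic.default_scenario(seed=1))
sel = select_order(sim.dataset, K_range=(1, 2, 3), seed=1)
fit = sel.fits[sel.best_K]
labels, table = classify(fit, sample_ids=sim.dataset.sample_ids,
                         delta=sim.dataset.delta)
```

A transcription of published two-component coefficient estimates for 99
colorectal-cancer genes ships with the package
(`aftmix.load_crc_coefficients()`); counting its active sets with
`active_genes` reproduces the published 83 / 18 active genes and 12 genes
inactive in both components.

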