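# fsva — frozen surrogate variable analysis for prediction problems

Batch effects — systematic non-biological variation tied to processing
date, technician, reagent lot — are a leading cause of failed genomic
classifiers. Population-scale corrections assume the biological groups are
known and all samples are in hand; neither holds in prediction, where the
group is what you want to predict and samples arrive one at a time. `fsva`
removes batch effects in exactly that setting: it learns the confounding
structure of a training database with surrogate variable analysis (SVA),
then *freezes* the learned quantities and uses them to clean individual new
samples before classification.

## The method in brief

Expression data follow `X = B·S + Γ·G + U`: outcome design `S` (known in
the training set), latent confounders `G` with coefficients `Γ`, noise `U`.
Training-side SVA alternates (i) empirical-Bayes estimation of each
feature's probability `π_w = (1 − π_b)·π_γ` of being confounder- but not
outcome-associated, and (ii) an SVD of the row-weighted matrix
`diag(π_w)·X`, whose leading right singular vectors estimate `G`. The
database is cleaned as `X − Γ̂·Ĝ` and a classifier (nearest shrunken
centroids) is trained on it.

For a new sample `x` with unknown class and batch, two frozen modes
estimate its surrogate values `ĝ` and return `x − Γ̂·ĝ`:

* **exact** — append `x` to the retained training matrix and recompute the
  weighted SVD with the frozen weights (one decomposition per sample);
* **fast** — pre-multiply by the frozen projection `P = D⁻¹·Uᵀ·Ŵ`, which
  maps any column onto the training right singular vectors (no
  decomposition; approximation error shrinks as the database grows).

Details, assumptions and numerical choices are in
[docs/methods.md](docs/methods.md).

## Worked example

```python
import numpy as np
import fsva

# a confounded training database: batch/outcome correlation 0.6,
# 1000 features, 100 database samples, 100 incoming samples
ds = fsva.simulate_dataset(scenario=1, rho=0.6, n_db=100, n_new=100,
                           m=1000, seed=1)
S = fsva.build_design(ds.outcome_db.astype(str))
fit = fsva.irwsva_fit(ds.X_db, S, n_sv=1)
print(round(abs(np.corrcoef(fit.G_hat[0], ds.batch_db)[0, 1]), 3))

clean_db = fsva.clean_training(ds.X_db, fit)
model = fsva.build_frozen_model(ds.X_db, fit)
clf_raw = fsva.nsc_train(ds.X_db, ds.outcome_db.astype(str), seed=1)
clf = fsva.nsc_train(clean_db, ds.outcome_db.astype(str), seed=1)

y_new = ds.outcome_new.astype(str)
for name, X in [("none", ds.X_new),
                ("fsva_fast", fsva.fsva_fast(model, ds.X_new)),
                ("fsva_exact", fsva.fsva_exact(model, ds.X_new))]:
    use = clf_raw if name == "none" else clf
    print(name, float(np.mean(fsva.nsc_predict(use, X) == y_new)))
```

prints

```
0.937
none 0.7
fsva_fast 0.99
fsva_exact 1.0
```

i.e. the first surrogate variable recovers the unobserved batch label
(|correlation| 0.937 despite the 0.6 batch–outcome confounding), and frozen
correction of the new samples lifts out-of-sample accuracy from 0.70
(batch-confounded) to 0.99–1.00.

The same pipeline is available from the shell:

```sh
fsva simulate --scenario 1 --rho 0.6 --m 1000 --seed 1 --out sim/
fsva fit --expr sim/database.tsv --pheno sim/pheno_database.tsv \
         --n-sv 1 --seed 1 --out model/
fsva apply --model model/ --expr sim/new_samples.tsv --mode fast --out clean.tsv
fsva benchmark --scenarios 1 --rhos 0.2:0.8:0.2 --reps 20 --m 1000 \
         --seed 1 --out bench.tsv
```

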