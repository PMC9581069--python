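# hierridge

Two-level hierarchical ridge regression for integrating feature-level prior
information ("meta-features") into high-dimensional prediction.

## The problem

Genomic prediction models — an epigenetic clock built from methylation
probes, a mortality classifier built from expression arrays — usually ignore
what is already known *about* each feature: which gene a probe maps to,
which pathway or curated signature a gene belongs to, effect estimates from
earlier studies.  `hierridge` lets that prior knowledge enter the model
directly.  Alongside the n × p feature matrix **X** and outcome **y**, it
takes a p × q meta-feature matrix **Z** whose row j describes feature j, and
fits

$$
\min_{\beta,\gamma}\;
\tfrac12\lVert y - X\beta\rVert_2^2
+ \tfrac{\lambda_1}{2}\lVert \beta - Z\gamma\rVert_2^2
+ \tfrac{\lambda_2}{2}\lVert \gamma\rVert_2^2 ,
\qquad \lambda_1,\lambda_2 > 0 .
$$

Feature coefficients are shrunk toward a meta-feature-determined mean
$Z\gamma$ instead of toward zero, so features with similar annotation
profiles borrow strength from one another; $\gamma$ is itself ridge-shrunk.
Substituting $\phi = \beta - Z\gamma$ reduces the problem to a single ridge
regression on the augmented design $\tilde X = [X, XZ]$ with block penalty
$\Lambda = \mathrm{diag}(\lambda_1 I_p, \lambda_2 I_q)$, solved exactly
($\hat\theta = (\tilde X^\top\tilde X + \Lambda)^{-1}\tilde X^\top y$, via a
dual form when $p+q>n$) or by cyclic coordinate descent; then
$\hat\beta = \hat\phi + Z\hat\gamma$.  $(\lambda_1,\lambda_2)$ are tuned
jointly by k-fold cross-validation on a 2-D grid that always contains the
standard-ridge submodel ($\lambda_2=\infty$), so uninformative meta-features
cost essentially nothing.  Gaussian and logistic (binomial) outcomes are
supported; closed forms for orthonormal special designs, the three
simulation designs used to evaluate the method, and a benchmark harness are
included.

## Worked example

```python
import numpy as np
from sklearn.metrics import r2_score
from hierridge import HierarchicalRidge
from hierridge.simulate import discrete_scenario, simulate

# pathway-indicator design: 400 features in 6 overlapping groups,
# group effects gamma = 0.1, moderately informative (SNR_gamma = 1)
ds = simulate(discrete_scenario(n=200, n_test=500, p=400, q=6,
                                snr_gamma=1.0, seed=7))

model = HierarchicalRidge(ds.y_train, ds.X_train, ds.Z)
cv = model.fit_cv(k=10, seed=7, n_lambda=10)
print(cv.cv.summary())

r2_two = r2_score(ds.y_test, cv.predict(ds.X_test))
ridge = HierarchicalRidge(ds.y_train, ds.X_train).fit_cv(k=10, seed=7, n_lambda=10)
r2_ridge = r2_score(ds.y_test, ridge.predict(ds.X_test))
print(f"test R2  two-level: {r2_two:.3f}   standard ridge: {r2_ridge:.3f}")
```

prints

```
10-fold CV (gaussian, metric=mse, mode=grid)
  grid: (10, 11), seed=7
  best pair: lambda1=119.104, lambda2=260.106
  best mean loss: 3.38637 (se 0.26)
test R2  two-level: 0.877   standard ridge: 0.737
```

CV lands on a finite $(\lambda_1,\lambda_2)$ pair — the meta-features carry
signal, so the two-level fit is chosen over the standard-ridge column of the
grid and improves held-out R² from 0.74 to 0.88.  The fitted meta-feature
coefficients track the generating value 0.1:

```
meta-feature coefficients (gamma):
  z0   0.0886   z1   0.0515   z2   0.0979
  z3   0.0885   z4   0.1081   z5   0.1273
```

`cv.results.to_frames()` returns coefficient tables
(feature_id, beta_hat, phi_hat) and (meta_feature_id, gamma_hat);
`model = HierarchicalRidge.from_frames(y, X_df, Z_df)` aligns Z rows to X
columns by feature ID.  For binary outcomes pass `family="binomial"` and use
`predict_proba`.

## Command line

```bash
hierridge simulate --design discrete --n 400 --p 2000 --q 6 --snr 1.0 --seed 1 --out data/
hierridge fit --x data/X_train.tsv --y data/y_train.txt --z data/Z.tsv \
              --family gaussian --k 10 --n-lambda 20 --seed 1 --out fit/
hierridge predict --x data/X_test.tsv --fit-dir fit/ --out predictions.txt
hierridge benchmark --design discrete --reps 50 --out results.tsv
hierridge oracle-check
```

`fit` accepts dense TSV/CSV (header + index IDs) or sparse MatrixMarket
matrices with `.rows`/`.cols` ID sidecars, and meta-features either as a
numeric matrix (`--z`, rows aligned to X columns by ID) or as feature→group
annotations (`--z-groups`, two-column TSV or GMT) expanded to indicator
columns, optionally column-sum-normalized (`--normalize-z`) so each
$\hat\gamma_j$ reads as the average effect of group j's features.  Every fit
writes a JSON manifest (penalties, seed, convergence, timing) sufficient to
reproduce the run.

See `docs/methods.md` for the model's assumptions, the closed-form special
cases, tuning defaults, and what the synthetic designs do and do not
emulate.

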