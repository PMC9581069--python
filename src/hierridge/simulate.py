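"""Synthetic data generators for evaluating meta-feature integration.

Three generative designs are provided, mirroring the settings under which
two-level ridge regression is expected to help: feature effects ``beta`` are
drawn around a meta-feature-determined mean,

    beta ~ N_p(Z gamma, sigma_beta^2 I_p),

so the informativeness of Z for the coefficients is a controllable dial, the
signal-to-noise ratio

    SNR_gamma = gamma' Sigma_Z gamma / sigma_beta^2,

with Sigma_Z the empirical covariance of the realized Z.  Given gamma, Z and
a target SNR_gamma, ``solve_sigma_beta`` inverts this definition exactly.

Designs:

* ``discrete``   — binary pathway-membership Z (iid Bernoulli entries,
  20% density by default, q = 6, gamma = 0.1 * 1_6), Gaussian outcome.
* ``continuous`` — quantitative Z with iid (or AR(1)-correlated) Gaussian
  rows, a sparse structured gamma = 0.01*(1_50, 0_25, 3_25, 1_25, 0_{q-150}),
  Gaussian outcome.
* ``binary``     — the continuous-Z design with a Bernoulli outcome through
  the logistic link.

Subject features have AR(1)-correlated columns, X rows ~ N(0, Sigma_X) with
(Sigma_X)_{ij} = rho_X^{|i-j|}; the outcome is y = mu0 + X beta + eps with
eps ~ N(0, sigma_y^2) (or Bernoulli{logistic(mu0 + X beta)}).  A matching
independent test set is always generated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.metrics import r2_score, roc_auc_score

log = logging.getLogger(__name__)

__all__ = [
    "SimScenario",
    "SimDataset",
    "discrete_scenario",
    "continuous_scenario",
    "binary_scenario",
    "default_continuous_gamma",
    "solve_sigma_beta",
    "simulate",
    "benchmark",
]


@dataclass(frozen=True)
class SimScenario:
    """Full generative specification of one simulated study."""

    n: int = 400
    n_test: int = 1000
    p: int = 2000
    q: int = 6
    z_type: str = "discrete"  # discrete | continuous
    z_density: float = 0.2
    gamma: np.ndarray | None = None
    snr_gamma: float = 1.0
    rho_X: float = 0.5
    rho_Z: float = 0.0
    mu0: float = 0.2
    sigma_y: float = 1.0
    family: str = "gaussian"
    seed: int = 0

    def __post_init__(self):
        if not (abs(self.rho_X) < 1 and abs(self.rho_Z) < 1):
            raise ValueError("AR(1) parameters must satisfy |rho| < 1")
        if self.snr_gamma <= 0:
            raise ValueError("snr_gamma must be > 0")
        if not 0 < self.z_density <= 1:
            raise ValueError("z_density must be in (0, 1]")
        if self.z_type not in ("discrete", "continuous"):
            raise ValueError("z_type must be 'discrete' or 'continuous'")

    def resolve_gamma(self) -> np.ndarray:
        if self.gamma is not None:
            g = np.asarray(self.gamma, dtype=float).ravel()
            if g.size != self.q:
                raise ValueError(f"gamma has length {g.size}, expected q={self.q}")
            return g
        if self.z_type == "discrete":
            return np.full(self.q, 0.1)
        return default_continuous_gamma(self.q)


@dataclass
class SimDataset:
    """One realized dataset (train + test) with its generative truth."""

    X_train: np.ndarray
    y_train: np.ndarray
    X_test: np.ndarray
    y_test: np.ndarray
    Z: np.ndarray
    beta_true: np.ndarray
    gamma_true: np.ndarray
    sigma_beta: float
    scenario: SimScenario = field(repr=False, default=None)


def discrete_scenario(**overrides) -> SimScenario:
    """Pathway-indicator design defaults: p=2000, q=6, gamma=0.1, mu0=0.2."""
    base = dict(z_type="discrete", p=2000, q=6, mu0=0.2, family="gaussian")
    base.update(overrides)
    return SimScenario(**base)


def continuous_scenario(**overrides) -> SimScenario:
    """Quantitative-Z design defaults: p=2000, q=150, structured gamma, mu0=0.5."""
    base = dict(z_type="continuous", p=2000, q=150, mu0=0.5, family="gaussian")
    base.update(overrides)
    return SimScenario(**base)


def binary_scenario(**overrides) -> SimScenario:
    """Binary-outcome design: the continuous-Z design with a logistic outcome."""
    base = dict(z_type="continuous", p=2000, q=150, mu0=0.5, family="binomial")
    base.update(overrides)
    return SimScenario(**base)


def default_continuous_gamma(q: int) -> np.ndarray:
    """Structured default gamma: 0.01 * (1_50, 0_25, 3_25, 1_25, 0_...).

    The four leading blocks cover 125 entries (100 of them nonzero); the
    remaining q - 125 entries are zero, so growing q only adds noise
    meta-features.  Requires q >= 150, the smallest size of this design;
    supply an explicit gamma for smaller q.
    """
    if q < 150:
        raise ValueError(
            f"the default structured gamma needs q >= 150 (got q={q}); "
            "supply an explicit gamma for smaller q"
        )
    return 0.01 * np.concatenate(
        [np.ones(50), np.zeros(25), 3 * np.ones(25), np.ones(25), np.zeros(q - 125)]
    )


def solve_sigma_beta(gamma, Z, snr_gamma: float) -> float:
    """Invert the SNR definition: sigma_beta = sqrt(gamma' Sigma_Z gamma / SNR).

    Sigma_Z is the empirical covariance of the realized Z (rows = features).
    """
    if snr_gamma <= 0:
        raise ValueError("snr_gamma must be > 0")
    gamma = np.asarray(gamma, dtype=float).ravel()
    Z = np.asarray(Z, dtype=float)
    Sigma_Z = np.cov(Z, rowvar=False)
    Sigma_Z = np.atleast_2d(Sigma_Z)
    quad = float(gamma @ Sigma_Z @ gamma)
    if quad <= 0:
        raise ValueError(
            "meta-feature signal is zero: gamma lies in the null space of Sigma_Z"
        )
    return float(np.sqrt(quad / snr_gamma))


def _ar1_normal(rng: np.random.Generator, n: int, p: int, rho: float) -> np.ndarray:
    """n draws from N_p(0, Sigma) with Sigma_ij = rho^{|i-j|}, by the exact
    AR(1) recursion (columnwise, vectorized over rows)."""
    X = np.empty((n, p))
    eps = rng.standard_normal((n, p))
    X[:, 0] = eps[:, 0]
    if p > 1 and rho != 0.0:
        s = np.sqrt(1.0 - rho**2)
        for j in range(1, p):
            X[:, j] = rho * X[:, j - 1] + s * eps[:, j]
    elif p > 1:
        X[:, 1:] = eps[:, 1:]
    return X


def _draw_discrete_Z(rng, p, q, density, max_tries=100):
    Z = (rng.random((p, q)) < density).astype(float)
    for _ in range(max_tries):
        zero = np.flatnonzero(Z.sum(axis=0) == 0)
        if not zero.size:
            return Z
        log.info("resampling %d all-zero meta-feature column(s)", zero.size)
        Z[:, zero] = (rng.random((p, zero.size)) < density).astype(float)
    raise RuntimeError("could not draw meta-feature columns with nonzero entries")


def simulate(scenario: SimScenario) -> SimDataset:
    """Generate one train/test dataset under the scenario's design."""
    sc = scenario
    rng = np.random.default_rng(sc.seed)
    gamma = sc.resolve_gamma()

    if sc.z_type == "discrete":
        Z = _draw_discrete_Z(rng, sc.p, sc.q, sc.z_density)
    else:
        Z = _ar1_normal(rng, sc.p, sc.q, sc.rho_Z)

    sigma_beta = solve_sigma_beta(gamma, Z, sc.snr_gamma)
    beta = Z @ gamma + sigma_beta * rng.standard_normal(sc.p)

    n_all = sc.n + sc.n_test
    X = _ar1_normal(rng, n_all, sc.p, sc.rho_X)
    lin = sc.mu0 + X @ beta

    if sc.family == "gaussian":
        y = lin + sc.sigma_y * rng.standard_normal(n_all)
    elif sc.family == "binomial":
        for attempt in range(100):
            y = (rng.random(n_all) < _expit(lin)).astype(float)
            ytr, yte = y[: sc.n], y[sc.n :]
            if 0 < ytr.sum() < sc.n and 0 < yte.sum() < sc.n_test:
                break
            log.warning("degenerate binary outcome draw; resampling (attempt %d)", attempt + 1)
        else:
            raise RuntimeError("binary outcome degenerate in every resample")
    else:
        raise ValueError(f"unknown family {sc.family!r}")

    return SimDataset(
        X_train=X[: sc.n],
        y_train=y[: sc.n],
        X_test=X[sc.n :],
        y_test=y[sc.n :],
        Z=Z,
        beta_true=beta,
        gamma_true=gamma,
        sigma_beta=sigma_beta,
        scenario=sc,
    )


def _expit(x):
    from scipy.special import expit

    return expit(np.clip(x, -30, 30))


# ---------------------------------------------------------------------------
# benchmark harness
# ---------------------------------------------------------------------------

_METHODS = ("twolevel", "ridge", "augmented")


def benchmark(
    scenario: SimScenario,
    *,
    methods=_METHODS,
    reps: int = 50,
    k: int = 10,
    n_lambda: int = 10,
    min_ratio: float = 1e-5,
    seed: int | None = None,
    external_predictions=None,
) -> pd.DataFrame:
    """Monte-Carlo comparison of estimators under a simulation scenario.

    For each replication r the scenario is realized with seed ``seed + r``,
    each method's penalties are tuned by k-fold CV on the training set, and
    held-out performance (test R^2 for Gaussian outcomes, test AUC for
    binomial) is computed on the independent test set.  Returns a tidy frame
    with columns (rep, method, metric, value).

    ``external_predictions`` maps a method name to a callable
    ``f(dataset, rep) -> test predictions`` so comparator methods fit
    outside this package can be scored on identical data.
    """
    from .model import HierarchicalRidge

    base_seed = scenario.seed if seed is None else seed
    metric = "test_r2" if scenario.family == "gaussian" else "test_auc"
    rows = []
    for r in range(reps):
        ds = simulate(replace(scenario, seed=base_seed + r))
        for method in methods:
            if external_predictions and method in external_predictions:
                pred = np.asarray(external_predictions[method](ds, r)).ravel()
            else:
                pred = _fit_predict(ds, method, k=k, n_lambda=n_lambda,
                                     min_ratio=min_ratio, cv_seed=base_seed + r)
            if scenario.family == "gaussian":
                value = r2_score(ds.y_test, pred)
            else:
                value = roc_auc_score(ds.y_test, pred)
            rows.append({"rep": r, "method": method, "metric": metric, "value": value})
    return pd.DataFrame(rows)


def _fit_predict(ds: SimDataset, method: str, *, k, n_lambda, min_ratio, cv_seed):
    from .model import HierarchicalRidge

    sc = ds.scenario
    if method == "ridge":
        model = HierarchicalRidge(ds.y_train, ds.X_train, None, family=sc.family)
        cv = model.fit_cv(k=k, seed=cv_seed, n_lambda=n_lambda, min_ratio=min_ratio)
        return cv.predict(ds.X_test)
    if method == "twolevel":
        model = HierarchicalRidge(ds.y_train, ds.X_train, ds.Z, family=sc.family)
        cv = model.fit_cv(k=k, seed=cv_seed, n_lambda=n_lambda, min_ratio=min_ratio)
        return cv.predict(ds.X_test)
    if method == "augmented":
        # single-penalty ridge on the augmented design [X, XZ] with every
        # column (including the XZ block) standardized, the glmnet
        # convention; equal shrinkage of phi and gamma is what distinguishes
        # this comparator from the two-level model
        A_train = np.hstack([ds.X_train, ds.X_train @ ds.Z])
        A_test = np.hstack([ds.X_test, ds.X_test @ ds.Z])
        model = HierarchicalRidge(ds.y_train, A_train, None, family=sc.family)
        cv = model.fit_cv(k=k, seed=cv_seed, n_lambda=n_lambda, min_ratio=min_ratio)
        return cv.predict(A_test)
    raise ValueError(f"unknown method {method!r}")
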