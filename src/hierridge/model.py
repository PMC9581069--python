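"""Model and results objects for two-level hierarchical ridge regression.

The model shrinks first-level coefficients ``beta`` toward a linear function
``Z gamma`` of feature-level "meta-features" (pathway memberships, prior
effect sizes, probe-to-gene groupings), while ``gamma`` itself is ridge-shrunk
toward zero:

    minimize (1/2)||y - X beta||^2 + (lambda1/2)||beta - Z gamma||^2
                                   + (lambda2/2)||gamma||^2.

Fitting goes through the single-level reformulation on the augmented design
[X, XZ]; estimates of beta are recovered as ``beta = phi + Z gamma``.
Standard ridge regression is the submodel with lambda2 = inf (or Z absent).

Typical use::

    model = HierarchicalRidge(y, X, Z)
    res = model.fit(lambda1=10.0, lambda2=100.0)
    cv = model.fit_cv(k=10, seed=1)
    print(cv.results.summary())
    yhat = cv.results.predict(X_new)
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp

from . import solvers
from .crossval import CVResult, cross_validate
from .families import get_family
from .glm import fit_glm
from .penalties import PenaltyGrid, PenaltyPair

__all__ = ["HierarchicalRidge", "HierRidgeResults", "HierRidgeCVResults"]


class HierarchicalRidge:
    """Two-level ridge regression model with meta-features.

    Parameters
    ----------
    endog : (n,) array
        Outcome; continuous for ``family="gaussian"``, 0/1 for
        ``family="binomial"``.
    exog : (n, p) array or sparse matrix
        Subject-level features.  Columns are standardized to mean 0,
        variance 1 at construction (scale-only for sparse input); constant
        columns are rejected.
    meta : (p, q) array, optional
        Meta-feature matrix Z, one row per feature.  ``None`` gives standard
        ridge regression.
    normalize_meta : bool
        Divide each (nonnegative) Z column by its sum, so each gamma_j is
        interpretable as the average effect of the features in group j.
    rescale_augmented : bool
        Opt-in variant that scales the XZ block to unit variance before
        penalizing (its columns are already exactly mean-zero because X is
        standardized).  Equivalent to per-column penalties lambda2 * var(XZ_j)
        on the raw product; gamma is reported back on the raw-XZ scale so
        ``beta = phi + Z gamma`` always holds.  Default off: the closed-form
        special cases hold on the raw product.
    """

    def __init__(
        self,
        endog,
        exog,
        meta=None,
        family="gaussian",
        *,
        normalize_meta: bool = False,
        rescale_augmented: bool = False,
        feature_names=None,
        meta_names=None,
    ):
        self.family = get_family(family)
        y = self.family.validate(endog)
        self.data = solvers.standardize(exog, y, center_y=self.family.name == "gaussian")
        self.n, self.p = self.data.X.shape

        if meta is not None:
            Z = np.asarray(meta, dtype=float) if not sp.issparse(meta) else meta.toarray()
            if Z.ndim == 1:
                Z = Z[:, None]
            if Z.shape[0] != self.p:
                raise ValueError(
                    f"meta-feature matrix has {Z.shape[0]} rows but X has {self.p} features"
                )
            if not np.all(np.isfinite(Z)):
                raise ValueError("meta-feature matrix contains non-finite values")
            if normalize_meta:
                if np.any(Z < 0):
                    raise ValueError("column-sum normalization requires nonnegative Z")
                sums = Z.sum(axis=0)
                zero = np.flatnonzero(sums == 0)
                if zero.size:
                    raise ValueError(
                        f"all-zero meta-feature column(s) {zero.tolist()} cannot be normalized"
                    )
                Z = Z / sums
            self.meta = Z if Z.shape[1] else None
        else:
            self.meta = None
        self.q = 0 if self.meta is None else self.meta.shape[1]
        self.normalize_meta = normalize_meta
        self.rescale_augmented = rescale_augmented

        self.feature_names = (
            list(feature_names) if feature_names is not None else [f"x{j}" for j in range(self.p)]
        )
        if len(self.feature_names) != self.p:
            raise ValueError("feature_names length does not match number of features")
        self.meta_names = (
            list(meta_names) if meta_names is not None else [f"z{j}" for j in range(self.q)]
        )
        if len(self.meta_names) != self.q:
            raise ValueError("meta_names length does not match number of meta-features")
        self._endog_raw = np.asarray(endog, dtype=float).ravel()
        self._exog_raw = exog

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_frames(cls, y, X: pd.DataFrame, Z: pd.DataFrame | None = None, **kwargs):
        """Build from pandas objects, aligning Z rows to X columns by ID.

        ``Z``'s index must cover every column of ``X``; rows are reordered to
        match (alignment by identifier, never by position).
        """
        X = pd.DataFrame(X)
        if Z is not None:
            Z = pd.DataFrame(Z)
            missing = [c for c in X.columns if c not in Z.index]
            if missing:
                raise ValueError(
                    f"meta-feature rows missing for {len(missing)} feature(s): "
                    f"{missing[:10]}{'...' if len(missing) > 10 else ''}"
                )
            Z = Z.loc[X.columns]
            kwargs.setdefault("meta_names", list(Z.columns))
        y = np.asarray(y)
        return cls(
            y,
            X.to_numpy(dtype=float),
            Z.to_numpy(dtype=float) if Z is not None else None,
            feature_names=list(X.columns),
            **kwargs,
        )

    # -- fitting -----------------------------------------------------------

    def _augmented(self):
        if not hasattr(self, "_Xt"):
            Xt = solvers.build_augmented(self.data.X, self.meta)
            if self.rescale_augmented:
                if sp.issparse(Xt):
                    Xt = Xt.toarray()
                s = Xt[:, self.p :].std(axis=0)
                if np.any(s <= 0):
                    raise ValueError("cannot rescale: an XZ column has zero variance")
                Xt = np.hstack([Xt[:, : self.p], Xt[:, self.p :] / s])
                self._xz_scales = s
            else:
                self._xz_scales = None
            self._Xt = Xt
        return self._Xt

    def fit(
        self,
        lambda1: float,
        lambda2: float = np.inf,
        *,
        method: str = "auto",
        tol: float = 1e-7,
        max_sweeps: int = 2000,
        start=None,
    ) -> "HierRidgeResults":
        """Fit at a fixed penalty pair.

        ``method`` is "auto" (exact closed form, primal or dual as size
        dictates), "closed_form", or "cd" (cyclic coordinate descent).
        ``lambda2=inf`` fits the standard-ridge submodel by dropping the
        meta-feature block.
        """
        pen = lambda1 if isinstance(lambda1, PenaltyPair) else PenaltyPair(lambda1, lambda2)
        use_meta = self.meta is not None and not pen.is_ridge
        Z = self.meta if use_meta else None
        Xt = self._augmented() if use_meta else self.data.X
        q = self.q if use_meta else 0
        lamvec = pen.vector(self.p, q) if use_meta else np.full(self.p, pen.lambda1)

        if self.family.name == "gaussian":
            if method in ("auto", "closed_form"):
                theta = solvers.solve_closed_form(Xt, self.data.y, lamvec)
                n_iter, converged = 0, True
                obj = solvers.objective_value(Xt, self.data.y, theta, lamvec)
            elif method == "cd":
                info = solvers.solve_cd(
                    Xt, self.data.y, lamvec, theta0=start, tol=tol, max_sweeps=max_sweeps
                )
                theta, n_iter, converged = info.theta, info.n_iter, info.converged
                obj = float(info.objective_path[-1])
            else:
                raise ValueError(f"unknown method {method!r}")
            intercept = self.data.y_mean
            deviance = None
        else:
            gf = fit_glm(
                Xt,
                self.data.y,
                lamvec,
                self.family,
                theta0=start,
                method="cd" if method == "cd" else "closed_form",
            )
            theta, n_iter, converged = gf.theta, gf.n_iter, gf.converged
            obj, intercept, deviance = gf.objective_value, gf.intercept, gf.deviance

        phi = theta[: self.p]
        gamma = theta[self.p :]
        if use_meta and self.rescale_augmented:
            gamma = gamma / self._xz_scales  # back to the raw-XZ scale
        beta = phi + (Z @ gamma if use_meta else 0.0)
        return HierRidgeResults(
            self, pen, phi, gamma, beta, float(intercept), obj, n_iter, converged, deviance
        )

    def fit_cv(
        self,
        *,
        grid: PenaltyGrid | None = None,
        k: int = 10,
        seed: int = 0,
        tied: bool = False,
        n_lambda: int = 20,
        min_ratio: float = 1e-5,
        lambda_max_factor: float = 1e3,
        include_ridge_row: bool = True,
        one_se: bool = False,
    ) -> "HierRidgeCVResults":
        """Select (lambda1, lambda2) by k-fold CV, then refit on all data.

        ``one_se=True`` refits at the most parsimonious pair within one
        standard error of the minimum instead of the minimizer itself.
        """
        cv = cross_validate(
            self._exog_raw if not sp.issparse(self._exog_raw) else self._exog_raw,
            self._endog_raw,
            self.meta,
            grid=grid,
            k=k,
            family=self.family,
            seed=seed,
            tied=tied,
            n_lambda=n_lambda,
            min_ratio=min_ratio,
            lambda_max_factor=lambda_max_factor,
            include_ridge_row=include_ridge_row,
        )
        chosen = cv.one_se_pair if one_se else cv.best_pair
        results = self.fit(chosen.lambda1, chosen.lambda2)
        return HierRidgeCVResults(cv, results)


class HierRidgeResults:
    """Fitted two-level ridge model.

    Attributes
    ----------
    phi, gamma, beta : arrays
        First-level offsets, meta-feature coefficients, and the implied
        feature coefficients ``beta = phi + Z gamma`` (on the standardized
        feature scale).
    intercept : float
        Unpenalized intercept (training outcome mean for the Gaussian
        model; profiled IRLS intercept for the binomial model).
    """

    def __init__(self, model, penalty, phi, gamma, beta, intercept, objective_value,
                 n_iter, converged, deviance=None):
        self.model = model
        self.penalty = penalty
        self.phi = np.asarray(phi)
        self.gamma = np.asarray(gamma)
        self.beta = np.asarray(beta)
        self.intercept = intercept
        self.objective_value = objective_value
        self.n_iter = n_iter
        self.converged = converged
        self.deviance = deviance

    @property
    def fittedvalues(self) -> np.ndarray:
        eta = self.intercept + np.asarray(self.model.data.X @ self.beta).ravel()
        return self.model.family.mean(eta)

    def _linpred(self, exog=None) -> np.ndarray:
        if exog is None:
            Xs = self.model.data.X
        else:
            Xs = self.model.data.transform(exog)
        return self.intercept + np.asarray(Xs @ self.beta).ravel()

    def predict(self, exog=None, which: str = "response") -> np.ndarray:
        """Predict for new (raw) feature rows using the training transform."""
        eta = self._linpred(exog)
        if which == "linear":
            return eta
        if which == "response":
            return self.model.family.mean(eta)
        raise ValueError(f"which must be 'response' or 'linear', got {which!r}")

    def predict_proba(self, exog=None) -> np.ndarray:
        """Event probabilities (binomial family only), strictly inside (0, 1)."""
        if self.model.family.name != "binomial":
            raise ValueError("predict_proba is only defined for the binomial family")
        return self.predict(exog, which="response")

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Coefficient tables: (feature-level, meta-feature-level)."""
        feat = pd.DataFrame(
            {"beta_hat": self.beta, "phi_hat": self.phi},
            index=pd.Index(self.model.feature_names, name="feature_id"),
        )
        met = pd.DataFrame(
            {"gamma_hat": self.gamma},
            index=pd.Index(self.model.meta_names[: self.gamma.size], name="meta_feature_id"),
        )
        return feat, met

    def summary(self, top: int = 10) -> str:
        m = self.model
        lines = [
            "Two-Level Hierarchical Ridge Regression Results",
            "=" * 55,
            f"family:        {m.family.name}",
            f"n obs:         {m.n}",
            f"p features:    {m.p}",
            f"q meta:        {m.q}",
            f"lambda1:       {self.penalty.lambda1:.6g}",
            f"lambda2:       {self.penalty.lambda2:.6g}"
            + ("  (standard-ridge submodel)" if self.penalty.is_ridge else ""),
            f"intercept:     {self.intercept:.6g}",
            f"||beta||_2:    {np.linalg.norm(self.beta):.6g}",
            f"converged:     {self.converged} (iterations: {self.n_iter})",
            f"objective:     {self.objective_value:.6g}",
        ]
        if self.deviance is not None:
            lines.append(f"deviance:      {self.deviance:.6g}")
        if self.gamma.size and self.gamma.size <= 25:
            lines.append("-" * 55)
            lines.append("meta-feature coefficients (gamma):")
            for name, g in zip(self.model.meta_names, self.gamma):
                lines.append(f"  {name:<20s} {g: .6g}")
        k = min(top, self.beta.size)
        idx = np.argsort(-np.abs(self.beta))[:k]
        lines.append("-" * 55)
        lines.append(f"largest |beta| ({k} of {self.beta.size}):")
        for j in idx:
            lines.append(f"  {self.model.feature_names[j]:<20s} {self.beta[j]: .6g}")
        return "\n".join(lines)


class HierRidgeCVResults:
    """CV surface plus the refit at the selected penalty pair."""

    def __init__(self, cv: CVResult, results: HierRidgeResults):
        self.cv = cv
        self.results = results

    @property
    def best_pair(self) -> PenaltyPair:
        return self.cv.best_pair

    def predict(self, exog=None, **kw):
        return self.results.predict(exog, **kw)

    def summary(self) -> str:
        return self.cv.summary() + "\n\n" + self.results.summary()

    def plot_cv_surface(self, ax=None):
        """Heatmap of the mean CV loss over the penalty lattice."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if self.cv.loss_mean.ndim == 1:
            ax.semilogx(self.cv.lambda1_path, self.cv.loss_mean, marker="o")
            ax.set_xlabel("lambda1")
            ax.set_ylabel(f"CV loss ({self.cv.metric})")
        else:
            im = ax.imshow(self.cv.loss_mean, aspect="auto", cmap="viridis")
            ax.figure.colorbar(im, ax=ax, label=f"CV loss ({self.cv.metric})")
            ax.set_xlabel("lambda2 index (last = inf)")
            ax.set_ylabel("lambda1 index")
        return ax
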