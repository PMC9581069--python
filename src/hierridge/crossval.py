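"""Joint (lambda1, lambda2) selection by k-fold cross-validation.

The search runs over a two-dimensional penalty lattice that by default
includes the lambda2 = inf column (the standard-ridge submodel), so the
two-level model can never do worse than standard ridge in CV loss on the
same folds — the mechanism behind "no cost" with uninformative
meta-features.

The engine works in the n x n kernel (dual) representation: for each
training fold it precomputes the Gram matrices K1 = XX', K2 = (XZ)(XZ)' and
the fold-to-validation cross products once, after which every grid point is
a single n_train x n_train symmetric solve

    alpha = (K1/lambda1 + K2/lambda2 + I)^{-1} y_c,
    theta = Lambda^{-1} Xt' alpha,

so the cost of the grid search is essentially independent of p and q.  For
binomial outcomes each grid point runs IRLS in the same kernel space with
the intercept profiled out under the working weights, warm-starting the
linear predictor from the adjacent grid point.

Standardization is refit on the training portion of every fold (no
leakage); the validation loss is mean squared error for Gaussian outcomes
and 1 - AUC (rank-based) for binomial outcomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import KFold, StratifiedKFold

from .families import get_family
from .penalties import PenaltyGrid, PenaltyPair
from .solvers import standardize

__all__ = ["make_folds", "default_grid", "CVResult", "cross_validate"]


def make_folds(n: int, k: int, stratify=None, seed: int = 0) -> np.ndarray:
    """Reproducible fold assignments (length-n integer vector in [0, k)).

    Fold sizes differ by at most one.  With ``stratify`` (a binary vector),
    class proportions are balanced across folds; every class must have at
    least k members, otherwise some fold would lack the class entirely and
    an error is raised.
    """
    if not 2 <= k <= n:
        raise ValueError(f"need 2 <= k <= n, got k={k}, n={n}")
    assign = np.empty(n, dtype=int)
    if stratify is not None:
        stratify = np.asarray(stratify).ravel()
        _, counts = np.unique(stratify, return_counts=True)
        if counts.min() < k:
            raise ValueError(
                f"cannot stratify: smallest class has {counts.min()} members < k={k} folds"
            )
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        split = splitter.split(np.zeros(n), stratify)
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        split = splitter.split(np.zeros(n))
    for f, (_, test_idx) in enumerate(split):
        assign[test_idx] = f
    return assign


def default_grid(
    X,
    y,
    Z=None,
    *,
    family="gaussian",
    n_lambda: int = 20,
    min_ratio: float = 1e-5,
    lambda_max_factor: float = 1e3,
    include_ridge_row: bool = True,
) -> PenaltyGrid:
    """Data-driven log-spaced penalty paths.

    The top of each path is ``lambda_max_factor`` times the largest absolute
    inner product between that block's columns and the null-model residual,
    which makes the heaviest-shrinkage corner essentially the null model;
    paths descend geometrically to ``lambda_max * min_ratio``.  ``X`` should
    already be standardized.
    """
    if n_lambda < 1:
        raise ValueError("n_lambda must be >= 1")
    fam = get_family(family)
    y = fam.validate(y)
    r0 = y - y.mean()

    def block_max(M, name):
        v = np.abs(np.asarray(M.T @ r0)).ravel()
        top = float(v.max()) if v.size else 0.0
        if top <= 0:
            raise ValueError(f"degenerate {name} block: all columns orthogonal to outcome")
        return top

    def path(lmax):
        if n_lambda == 1:
            return np.array([lmax])
        return np.geomspace(lmax, lmax * min_ratio, n_lambda)

    l1 = path(lambda_max_factor * block_max(X, "feature"))
    if Z is None:
        return PenaltyGrid(l1, np.array([1.0]), include_ridge_row=True)
    XZ = X @ Z
    l2 = path(lambda_max_factor * block_max(XZ, "meta-feature"))
    return PenaltyGrid(l1, l2, include_ridge_row=include_ridge_row)


@dataclass
class CVResult:
    """Cross-validation surface and the selected penalty pair.

    ``loss_mean``/``loss_se`` are indexed (lambda1, lambda2) in grid mode
    (the last lambda2 column is the inf/standard-ridge sentinel when
    present) and are 1-D in ``tied`` (augmented-ridge, lambda1 = lambda2)
    and ``ridge`` (no meta-features) modes.  Loss is MSE for Gaussian and
    1 - AUC for binomial outcomes; ``best_pair`` attains the minimum mean
    loss, with ties broken toward the lexicographically larger
    (more parsimonious) pair.
    """

    mode: str
    metric: str
    family: str
    lambda1_path: np.ndarray
    lambda2_path: np.ndarray | None
    loss_mean: np.ndarray
    loss_se: np.ndarray
    best_pair: PenaltyPair
    best_index: tuple
    fold_assignments: np.ndarray
    seed: int
    k: int
    one_se_pair: PenaltyPair = field(default=None)

    @property
    def best_loss(self) -> float:
        return float(self.loss_mean[self.best_index])

    def summary(self) -> str:
        lines = [
            f"{self.k}-fold CV ({self.family}, metric={self.metric}, mode={self.mode})",
            f"  grid: {self.loss_mean.shape}, seed={self.seed}",
            f"  best pair: lambda1={self.best_pair.lambda1:.6g}, "
            f"lambda2={self.best_pair.lambda2:.6g}",
            f"  best mean loss: {self.best_loss:.6g} "
            f"(se {float(self.loss_se[self.best_index]):.3g})",
        ]
        return "\n".join(lines)


def _select_best(loss_mean, pairs_of_index):
    """Minimum mean loss; ties go to the lexicographically larger pair."""
    lmin = np.nanmin(loss_mean)
    cand = np.argwhere(loss_mean <= lmin + 0.0)
    best = min(
        (tuple(ix) for ix in cand),
        key=lambda ix: (-pairs_of_index(ix).lambda1, -pairs_of_index(ix).lambda2),
    )
    return best


def _one_se_pair(loss_mean, loss_se, best_index, pairs_of_index):
    thresh = loss_mean[best_index] + loss_se[best_index]
    cand = np.argwhere(loss_mean <= thresh)
    best = min(
        (tuple(ix) for ix in cand),
        key=lambda ix: (-pairs_of_index(ix).lambda1, -pairs_of_index(ix).lambda2),
    )
    return pairs_of_index(best)


# ---------------------------------------------------------------------------
# kernel engine
# ---------------------------------------------------------------------------


def _kernel_irls(Klam, y, eta0, fam, tol=1e-7, max_iter=30):
    """IRLS for ridge-penalized logistic regression in kernel space.

    ``Klam`` = Xt Lambda^{-1} Xt' on the training fold.  The unpenalized
    intercept is profiled out under the working weights each iteration.
    Returns the converged training linear predictor plus the quantities
    needed to form validation predictions.
    """
    n = y.size
    eta = eta0.copy() if eta0 is not None else np.full(n, fam.null_intercept(y))
    state = None
    prev_obj = np.inf
    bad = 0
    for _ in range(max_iter):
        w, z = fam.irls(eta, y)
        wbar = w / w.sum()
        zbar = float(wbar @ z)
        kw = Klam @ wbar
        kww = float(wbar @ kw)
        # doubly (weighted-) centered kernel
        Kc = Klam - kw[None, :] - kw[:, None] + kww
        sw = np.sqrt(w)
        M = Kc * sw[:, None] * sw[None, :]
        M[np.diag_indices(n)] += 1.0
        u = cho_solve(cho_factor(M, lower=True, check_finite=False),
                      sw * (z - zbar), check_finite=False)
        v = sw * u
        Kcv = Kc @ v
        eta_new = zbar + Kcv  # weighted centering makes wbar'Kc = 0
        pen = float(v @ Kcv)
        obj = -fam.loglik(eta_new, y) + 0.5 * pen
        state = (zbar, kw, kww, v)
        d = float(np.max(np.abs(eta_new - eta)))
        eta = eta_new
        if d <= tol * (1.0 + float(np.max(np.abs(eta)))):
            break
        if obj > prev_obj + 1e-8:
            bad += 1
            if bad >= 2:  # diverging (near-separation at tiny penalties): stop
                break
        else:
            bad = 0
        prev_obj = obj
    return eta, state


def _validation_eta(state, Clam, wbar):
    """Validation linear predictor b0 + Xt_val theta from the kernel state.

    theta = Lambda^{-1}(Xt' - mu 1') v with mu the weighted column means, so
    Xt_val theta = Clam v - (Clam wbar)(1'v) and the profiled intercept
    contributes zbar - mu' theta = zbar - kw'v + kww (1'v).
    """
    zbar, kw, kww, v = state
    sv = float(v.sum())
    return zbar - float(kw @ v) + kww * sv + Clam @ v - (Clam @ wbar) * sv


class _FoldWork:
    """Per-fold standardization and Gram/cross-product precomputation."""

    def __init__(self, X, y, Z, tr, va, fam):
        center_y = fam.name == "gaussian"
        fd = standardize(X[tr], y[tr], center_y=center_y)
        self.y_tr = fd.y
        self.y_mean = fd.y_mean
        self.y_va = np.asarray(y, dtype=float)[va]
        Xtr = fd.X
        Xva = fd.transform(X[va])

        def dense(M):
            return M.toarray() if hasattr(M, "toarray") else np.asarray(M)

        self.K1 = dense(Xtr @ Xtr.T)
        self.C1 = dense(Xva @ Xtr.T)
        if Z is not None:
            XZtr = dense(Xtr @ Z)
            XZva = dense(Xva @ Z)
            self.K2 = XZtr @ XZtr.T
            self.C2 = XZva @ XZtr.T
        else:
            self.K2 = self.C2 = None
        self.n_tr = self.K1.shape[0]

    def kernels(self, pair: PenaltyPair):
        Klam = self.K1 / pair.lambda1
        Clam = self.C1 / pair.lambda1
        if self.K2 is not None and not pair.is_ridge:
            Klam = Klam + self.K2 / pair.lambda2
            Clam = Clam + self.C2 / pair.lambda2
        return Klam, Clam


def cross_validate(
    X,
    y,
    Z=None,
    *,
    grid: PenaltyGrid | None = None,
    k: int = 10,
    family="gaussian",
    seed: int = 0,
    tied: bool = False,
    stratify: str | None = "auto",
    n_lambda: int = 20,
    min_ratio: float = 1e-5,
    lambda_max_factor: float = 1e3,
    include_ridge_row: bool = True,
    irls_tol: float = 1e-7,
    irls_max: int = 30,
) -> CVResult:
    """k-fold CV of the two-level ridge model over a penalty lattice.

    ``Z=None`` tunes standard ridge over lambda1 only; ``tied=True`` ties
    lambda1 = lambda2 along the lambda1 path (the "augmented ridge"
    comparator, a single-penalty ridge on [X, XZ]).
    """
    fam = get_family(family)
    X = np.asarray(X, dtype=float) if not hasattr(X, "tocsr") else X
    y = fam.validate(y)
    n = X.shape[0]
    if Z is not None:
        Z = np.asarray(Z, dtype=float)

    strat = y if (fam.name == "binomial" and stratify == "auto") else (
        None if stratify in (None, "auto") else np.asarray(stratify)
    )
    folds = make_folds(n, k, strat, seed)

    if grid is None:
        fd_full = standardize(X, y, center_y=fam.name == "gaussian")
        grid = default_grid(
            fd_full.X,
            y,
            Z,
            family=fam,
            n_lambda=n_lambda,
            min_ratio=min_ratio,
            lambda_max_factor=lambda_max_factor,
            include_ridge_row=include_ridge_row,
        )

    l1p = grid.lambda1_path
    if Z is None:
        mode = "ridge"
        pairs = [PenaltyPair(l1, np.inf) for l1 in l1p]
        shape = (l1p.size,)
        index_of = lambda flat: (flat,)
        pair_of_index = lambda ix: pairs[ix[0]]
    elif tied:
        mode = "tied"
        pairs = [PenaltyPair(l1, l1) for l1 in l1p]
        shape = (l1p.size,)
        index_of = lambda flat: (flat,)
        pair_of_index = lambda ix: pairs[ix[0]]
    else:
        mode = "grid"
        l2p = grid.lambda2_full
        # traversal: lambda2 descending (inf sentinel first), lambda1 descending,
        # so logistic warm starts move between adjacent penalties
        pairs = []
        order = []
        cols = list(range(l2p.size))
        if grid.include_ridge_row:
            cols = [l2p.size - 1] + cols[:-1]
        for i2 in cols:
            for i1 in range(l1p.size):
                pairs.append(PenaltyPair(l1p[i1], l2p[i2]))
                order.append((i1, i2))
        shape = (l1p.size, l2p.size)
        pair_lookup = dict(zip(order, pairs))
        index_of = lambda flat: order[flat]
        pair_of_index = lambda ix: pair_lookup[tuple(ix)]

    loss = np.full((k,) + shape, np.nan)
    for f in range(k):
        tr = folds != f
        va = folds == f
        fw = _FoldWork(X, y, Z, tr, va, fam)
        eye = np.eye(fw.n_tr)
        eta_warm = None
        for flat, pair in enumerate(pairs):
            Klam, Clam = fw.kernels(pair)
            if fam.name == "gaussian":
                A = Klam + eye
                alpha = cho_solve(
                    cho_factor(A, lower=True, check_finite=False),
                    fw.y_tr,
                    check_finite=False,
                )
                pred = Clam @ alpha + fw.y_mean
                val_loss = float(np.mean((fw.y_va - pred) ** 2))
            else:
                eta_tr, state = _kernel_irls(
                    Klam, fw.y_tr, eta_warm, fam, tol=irls_tol, max_iter=irls_max
                )
                eta_warm = eta_tr
                w, _ = fam.irls(eta_tr, fw.y_tr)
                wbar = w / w.sum()
                eta_va = _validation_eta(state, Clam, wbar)
                val_loss = 1.0 - roc_auc_score(fw.y_va, eta_va)
            loss[(f,) + index_of(flat)] = val_loss

    loss_mean = loss.mean(axis=0)
    loss_se = loss.std(axis=0, ddof=1) / np.sqrt(k)
    best = _select_best(loss_mean, pair_of_index)
    result = CVResult(
        mode=mode,
        metric="mse" if fam.name == "gaussian" else "auc",
        family=fam.name,
        lambda1_path=l1p,
        lambda2_path=grid.lambda2_full if mode == "grid" else None,
        loss_mean=loss_mean,
        loss_se=loss_se,
        best_pair=pair_of_index(best),
        best_index=best,
        fold_assignments=folds,
        seed=seed,
        k=k,
        one_se_pair=_one_se_pair(loss_mean, loss_se, best, pair_of_index),
    )
    return result
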