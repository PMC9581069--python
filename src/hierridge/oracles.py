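"""Closed-form solutions of the two-level ridge model for special designs.

Under an orthonormal design (X'X = I_p) the standard ridge estimator is the
shrunken least-squares fit beta_ridge = X'y / (1 + lambda).  For particular
meta-feature matrices the two-level estimator also has an explicit form that
shows how information is "borrowed" across features sharing meta-feature
profiles.  These formulas are derived independently of the generic solver
(by block elimination of the augmented normal equations) and serve as
exactness oracles for it.

Throughout, with X'X = I_p the augmented normal equations reduce to

    gamma_hat = (Z'Z + t I_q)^{-1} Z' b,     t = lambda2 (1 + lambda1) / lambda1,
    beta_hat  = beta_ridge + lambda1/(1+lambda1) * Z gamma_hat,

where b = X'y = (1 + lambda1) * beta_ridge.  The three cases below specialize
this to (1) disjoint groups of two features, (2) two overlapping groups over
three features, and (3) a general Z with orthonormal columns (Z'Z = I_q).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "CASE1_Z",
    "CASE2_Z",
    "lambda_star",
    "case1_disjoint",
    "case2_overlapping",
    "case3_orthogonal",
    "orthonormal_design",
    "case3_instance",
    "ridge_orthonormal",
]

# group-indicator matrices of the two pedagogical cases
CASE1_Z = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0], [0.0, 1.0]])
CASE2_Z = np.array([[1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])


def _check_lams(lambda1: float, lambda2: float) -> tuple[float, float]:
    l1, l2 = float(lambda1), float(lambda2)
    if not (np.isfinite(l1) and np.isfinite(l2)) or l1 <= 0 or l2 <= 0:
        raise ValueError(f"penalties must be finite and > 0, got ({lambda1}, {lambda2})")
    return l1, l2


def lambda_star(case: int, lambda1: float, lambda2: float) -> float:
    """Scalar borrowing weight lambda* of the group-indicator cases.

    Case 1 (disjoint groups of size two): lambda1^2 / (2 lambda1 + lambda1 lambda2 + lambda2).
    Case 2 (overlapping pathways):        lambda1^2 / (3 lambda1 + lambda1 lambda2 + lambda2).

    lambda* is nonnegative, vanishes as lambda1 -> 0, and for fixed lambda1
    is strictly decreasing in lambda2 (stronger shrinkage of gamma means
    less pooling).
    """
    l1, l2 = _check_lams(lambda1, lambda2)
    if case == 1:
        return l1**2 / (2 * l1 + l1 * l2 + l2)
    if case == 2:
        return l1**2 / (3 * l1 + l1 * l2 + l2)
    raise ValueError("lambda_star is defined for case 1 or 2")


def case1_disjoint(beta_ridge, lambda1: float, lambda2: float) -> np.ndarray:
    """Two disjoint groups of two features each (p = 4, X'X = I_4).

    Each estimate equals its standard ridge estimate plus lambda* times the
    within-group sum of ridge estimates:

        beta_j = beta_j^r + lambda* (beta_a^r + beta_b^r),  {a, b} = j's group.
    """
    br = np.asarray(beta_ridge, dtype=float).ravel()
    if br.size != 4:
        raise ValueError(f"case 1 requires 4 ridge estimates, got {br.size}")
    ls = lambda_star(1, lambda1, lambda2)
    g1 = br[0] + br[1]
    g2 = br[2] + br[3]
    return br + ls * np.array([g1, g1, g2, g2])


def case2_overlapping(beta_ridge, lambda1: float, lambda2: float) -> np.ndarray:
    """Two overlapping groups over three features (p = 3, X'X = I_3).

    Feature 2 belongs to both groups.  Every estimate is a weighted sum of
    all three ridge estimates.  With t = lambda2 (1 + lambda1) / lambda1 and
    lambda* = lambda1^2 / (3 lambda1 + lambda1 lambda2 + lambda2)
    (= lambda1 / (3 + t)), block elimination gives exactly

        beta = beta^r + lambda* / (1 + t) * W beta^r,

        W = [[2 + t, 1 + t,    -1],
             [1 + t, 2(1+t), 1 + t],
             [-1,    1 + t, 2 + t]].

    The middle coefficient simplifies to the familiar pooled form
    beta_2^r + lambda* (beta_1^r + 2 beta_2^r + beta_3^r); the outer
    coefficients carry slightly asymmetric weights that reduce to
    (2, 1, -1) only in the limit t -> 0.
    """
    br = np.asarray(beta_ridge, dtype=float).ravel()
    if br.size != 3:
        raise ValueError(f"case 2 requires 3 ridge estimates, got {br.size}")
    l1, l2 = _check_lams(lambda1, lambda2)
    t = l2 * (1 + l1) / l1
    W = np.array(
        [
            [2 + t, 1 + t, -1.0],
            [1 + t, 2 * (1 + t), 1 + t],
            [-1.0, 1 + t, 2 + t],
        ]
    )
    return br + lambda_star(2, l1, l2) / (1 + t) * (W @ br)


def case3_orthogonal(beta_ridge, Z, lambda1: float, lambda2: float) -> np.ndarray:
    """General quantitative Z with orthonormal columns (X'X = I_p, Z'Z = I_q).

        beta = (I_p + lambda1^2 / (lambda1 lambda2 + lambda1 + lambda2) Z Z') beta^r.

    Z Z' is the matrix of pairwise meta-feature similarities (inner products
    of meta-feature profiles): information is borrowed across all features
    proportionally to their similarity.  Features with identical Z rows and
    equal ridge estimates receive identical borrowing increments.
    """
    br = np.asarray(beta_ridge, dtype=float).ravel()
    Z = np.asarray(Z, dtype=float)
    if Z.ndim != 2 or Z.shape[0] != br.size:
        raise ValueError(
            f"shape mismatch: Z is {Z.shape} but there are {br.size} ridge estimates"
        )
    l1, l2 = _check_lams(lambda1, lambda2)
    # all-zero Z (no information to borrow) is the degenerate allowed case
    if Z.shape[1] and np.any(Z) and not np.allclose(
        Z.T @ Z, np.eye(Z.shape[1]), atol=1e-10
    ):
        raise ValueError("case 3 requires Z with orthonormal columns (Z'Z = I_q)")
    c = l1**2 / (l1 * l2 + l1 + l2)
    return br + c * (Z @ (Z.T @ br))


# ---------------------------------------------------------------------------
# instance constructors for oracle cross-checks
# ---------------------------------------------------------------------------


def orthonormal_design(n: int, p: int, rng: np.random.Generator) -> np.ndarray:
    """First p columns of the Q factor of a random Gaussian n x p matrix.

    Gives X'X = I_p to machine precision, which the closed forms assume.
    Requires n >= p.
    """
    if n < p:
        raise ValueError(f"orthonormal design needs n >= p, got n={n}, p={p}")
    Q, R = np.linalg.qr(rng.standard_normal((n, p)))
    # fix signs for reproducibility
    return Q * np.sign(np.diag(R))


def case3_instance(
    n: int, p: int, q: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal X (n x p) and Z (p x q) with orthonormal columns."""
    if p < q:
        raise ValueError(f"need p >= q for orthonormal Z columns, got p={p}, q={q}")
    X = orthonormal_design(n, p, rng)
    Z = orthonormal_design(p, q, rng)
    return X, Z


def ridge_orthonormal(X, y, lam: float) -> np.ndarray:
    """Standard ridge estimator under X'X = I_p: X'y / (1 + lambda)."""
    if lam <= 0:
        raise ValueError("lambda must be > 0")
    return (np.asarray(X).T @ np.asarray(y, dtype=float).ravel()) / (1.0 + lam)
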