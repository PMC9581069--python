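"""Outcome families for the two-level ridge GLM.

Only the Gaussian (identity link) and binomial (logit link) families ship;
both use their canonical link.  The binomial working weights are floored to
keep the inner weighted least-squares problems well conditioned near fitted
probabilities of 0 or 1.
"""

from __future__ import annotations

import numpy as np

_ETA_CLIP = 30.0  # |linear predictor| beyond this saturates the logistic curve
_W_FLOOR = 1e-5


class Family:
    name: str = ""

    def validate(self, y: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def mean(self, eta: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def loglik(self, eta: np.ndarray, y: np.ndarray) -> float:
        raise NotImplementedError

    def deviance(self, eta: np.ndarray, y: np.ndarray) -> float:
        raise NotImplementedError

    def null_intercept(self, y: np.ndarray) -> float:
        raise NotImplementedError

    def irls(self, eta: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Working weights and working response at the current linear predictor."""
        raise NotImplementedError

    def __repr__(self) -> str:  # pragma: no cover
        return f"{type(self).__name__}()"


class Gaussian(Family):
    name = "gaussian"

    def validate(self, y):
        y = np.asarray(y, dtype=float).ravel()
        if not np.all(np.isfinite(y)):
            raise ValueError("outcome contains non-finite values")
        return y

    def mean(self, eta):
        return eta

    def loglik(self, eta, y):
        # unit dispersion; constants dropped
        return -0.5 * float(np.sum((y - eta) ** 2))

    def deviance(self, eta, y):
        return float(np.sum((y - eta) ** 2))

    def null_intercept(self, y):
        return float(np.mean(y))

    def irls(self, eta, y):
        return np.ones_like(y), y


class Binomial(Family):
    name = "binomial"

    def validate(self, y):
        y = np.asarray(y, dtype=float).ravel()
        vals = np.unique(y)
        if not np.all(np.isin(vals, [0.0, 1.0])):
            raise ValueError("binomial outcome must be coded 0/1")
        if vals.size < 2:
            raise ValueError("binomial outcome has a single class; both classes required")
        return y

    def mean(self, eta):
        # clipping keeps probabilities strictly inside (0, 1)
        from scipy.special import expit

        return expit(np.clip(eta, -_ETA_CLIP, _ETA_CLIP))

    def loglik(self, eta, y):
        eta = np.clip(eta, -_ETA_CLIP, _ETA_CLIP)
        return float(np.sum(y * eta - np.logaddexp(0.0, eta)))

    def deviance(self, eta, y):
        # saturated log-likelihood is 0 for 0/1 outcomes
        return -2.0 * self.loglik(eta, y)

    def null_intercept(self, y):
        pbar = float(np.clip(np.mean(y), 1e-10, 1 - 1e-10))
        return float(np.log(pbar / (1.0 - pbar)))

    def irls(self, eta, y):
        mu = self.mean(eta)
        w = np.clip(mu * (1.0 - mu), _W_FLOOR, None)
        z = eta + (y - mu) / w
        return w, z


_FAMILIES = {"gaussian": Gaussian, "binomial": Binomial}


def get_family(family) -> Family:
    """Resolve a family name or instance to a Family object."""
    if isinstance(family, Family):
        return family
    try:
        return _FAMILIES[str(family).lower()]()
    except KeyError:
        raise ValueError(
            f"unknown family {family!r}; choose from {sorted(_FAMILIES)}"
        ) from None
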