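"""Penalty containers for the two-level ridge model.

The model penalizes the first-level offsets ``phi`` with ``lambda1`` and the
meta-feature coefficients ``gamma`` with ``lambda2``.  ``lambda2 = inf`` is an
accepted sentinel meaning "standard ridge submodel": the meta-feature block is
dropped entirely rather than approximated with a huge penalty.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class PenaltyPair:
    """A single (lambda1, lambda2) penalty configuration.

    Both penalties must be strictly positive; ``lambda2 = numpy.inf`` selects
    the standard-ridge submodel (no meta-feature block).
    """

    lambda1: float
    lambda2: float = np.inf

    def __post_init__(self) -> None:
        l1, l2 = float(self.lambda1), float(self.lambda2)
        if not np.isfinite(l1) or l1 <= 0:
            raise ValueError(f"lambda1 must be finite and > 0, got {self.lambda1}")
        if np.isnan(l2) or l2 <= 0:
            raise ValueError(f"lambda2 must be > 0 (inf allowed), got {self.lambda2}")
        object.__setattr__(self, "lambda1", l1)
        object.__setattr__(self, "lambda2", l2)

    @property
    def is_ridge(self) -> bool:
        """True when this pair encodes the standard-ridge submodel."""
        return np.isinf(self.lambda2)

    def vector(self, p: int, q: int) -> np.ndarray:
        """Per-coordinate penalty vector for the augmented parameter theta."""
        if self.is_ridge and q > 0:
            raise ValueError("lambda2=inf drops the meta-feature block; q must be 0")
        return np.concatenate([np.full(p, self.lambda1), np.full(q, self.lambda2)])


def _check_path(path: np.ndarray, name: str) -> np.ndarray:
    path = np.asarray(path, dtype=float)
    if path.ndim != 1 or path.size == 0:
        raise ValueError(f"{name} must be a non-empty 1-D array")
    if not np.all(np.isfinite(path)) or np.any(path <= 0):
        raise ValueError(f"{name} must be strictly positive and finite")
    if path.size > 1 and not np.all(np.diff(path) < 0):
        raise ValueError(f"{name} must be strictly decreasing")
    return path


@dataclass
class PenaltyGrid:
    """Two-dimensional (lambda1, lambda2) tuning lattice.

    ``include_ridge_row`` appends the lambda2 = inf column so that the
    standard-ridge submodel is always part of the search space.
    """

    lambda1_path: np.ndarray
    lambda2_path: np.ndarray = field(default_factory=lambda: np.array([1.0]))
    include_ridge_row: bool = True

    def __post_init__(self) -> None:
        self.lambda1_path = _check_path(self.lambda1_path, "lambda1_path")
        self.lambda2_path = _check_path(self.lambda2_path, "lambda2_path")

    @property
    def lambda2_full(self) -> np.ndarray:
        """lambda2 path including the inf sentinel column when requested."""
        if self.include_ridge_row:
            return np.concatenate([self.lambda2_path, [np.inf]])
        return self.lambda2_path

    @property
    def shape(self) -> tuple[int, int]:
        return self.lambda1_path.size, self.lambda2_full.size
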