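"""Expected-improvement acquisition over a discrete candidate pool.

The objective is *minimized* (lower barrier = more reactive), so improvement
at a candidate is ``f_best - mu(x) - xi`` with exploration offset ``xi``:

    Z  = (f_best - mu(x) - xi) / sigma(x)
    EI = (f_best - mu(x) - xi) * Phi(Z) + sigma(x) * phi(Z)      (sigma > 0)
    EI = max(f_best - mu(x) - xi, 0)                             (sigma = 0)

All quantities are on the standardized output scale.  ``f_best`` is by
default the best *experimentally* verified value; noisy computational
observations inform the posterior but do not move the incumbent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Set

import numpy as np
from scipy.special import ndtr

from .gp_core import GPState, posterior_batch
from .substrate_space import Substrate


class AcquisitionError(ValueError):
    pass


class ExhaustedPoolError(AcquisitionError):
    """No eligible candidate remains in the pool."""


#: tolerance for negative variances surviving upstream clipping
_VAR_TOL = 1e-8


@dataclass(frozen=True)
class AcquisitionConfig:
    """EI settings: exploration offset ``xi`` (standardized units), >= 0."""

    xi: float = 0.01

    def __post_init__(self) -> None:
        if self.xi < 0:
            raise AcquisitionError(f"xi must be >= 0, got {self.xi}")


def expected_improvement(
    mean: np.ndarray | float,
    variance: np.ndarray | float,
    f_best: float,
    cfg: AcquisitionConfig = AcquisitionConfig(),
) -> np.ndarray | float:
    """EI for minimization; vectorized over candidates.

    Accepts scalars or arrays of posterior means/variances; returns the same
    shape.  Always non-negative; the zero-variance limit is handled
    analytically.
    """
    mean = np.asarray(mean, dtype=float)
    variance = np.asarray(variance, dtype=float)
    if np.any(variance < -_VAR_TOL):
        raise AcquisitionError(
            f"negative variance beyond clipping tolerance: {variance.min()}"
        )
    variance = np.maximum(variance, 0.0)
    sigma = np.sqrt(variance)
    improve = f_best - mean - cfg.xi

    scalar = sigma.ndim == 0
    sigma = np.atleast_1d(sigma)
    improve = np.atleast_1d(improve)
    ei = np.maximum(improve, 0.0)  # sigma == 0 limit
    pos = sigma > 0
    if np.any(pos):
        z = improve[pos] / sigma[pos]
        phi = np.exp(-0.5 * z * z) / np.sqrt(2.0 * np.pi)
        ei_pos = improve[pos] * ndtr(z) + sigma[pos] * phi
        ei = ei.astype(float)
        ei[pos] = np.maximum(ei_pos, 0.0)
    return float(ei[0]) if scalar else ei


def best_candidate(
    pool: Sequence[Substrate],
    X_pool: np.ndarray,
    state: GPState,
    f_best: float,
    cfg: AcquisitionConfig = AcquisitionConfig(),
    excluded: Set[Substrate] = frozenset(),
) -> Substrate:
    """The eligible pool member maximizing EI.

    ``X_pool`` holds the encoded feature rows aligned with ``pool``.  Ties are
    broken by pool order, which callers keep lexicographic in the substrate
    tuples, so the choice is deterministic.
    """
    eligible = np.array([s not in excluded for s in pool], dtype=bool)
    if not eligible.any():
        raise ExhaustedPoolError("every pool member is excluded")
    mean, var = posterior_batch(state, np.atleast_2d(X_pool))
    ei = np.asarray(expected_improvement(mean, var, f_best, cfg))
    ei = np.where(eligible, ei, -np.inf)
    return pool[int(np.argmax(ei))]
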