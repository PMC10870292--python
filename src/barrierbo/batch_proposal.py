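"""Kriging-believer batch proposal.

To propose a batch of ``b`` candidates from one fitted model, the EI argmax
is selected, the GP's own posterior mean there is appended as a provisional
("fantasy") observation, the posterior is updated, and the selection repeats.
Fantasy observations shrink the posterior variance around already-proposed
candidates, which spreads the batch without changing hyperparameters.

Hyperparameters are fitted once per batch from the real observations and held
fixed across the ``b`` fantasy iterations; only the training set grows.  The
fantasy updates use a rank-one extension of the Cholesky factor, so a whole
batch costs one factorization plus ``b`` cheap updates.  Because the fantasy
value *is* the posterior mean, these updates leave the posterior mean over
the pool unchanged and only reduce variance; the code nevertheless carries
the general update so the mechanism is explicit and testable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Set

import numpy as np
from scipy import linalg

from .acquisition import AcquisitionConfig, expected_improvement
from .gp_core import GPConfig, GPState, fit_hyperparameters, kernel_matrix, standardize
from .substrate_space import Substrate


class PartialBatchError(RuntimeError):
    """Eligible pool exhausted mid-batch; carries the proposals found."""

    def __init__(self, message: str, proposals: list[Substrate]):
        super().__init__(message)
        self.proposals = proposals


@dataclass
class BatchResult:
    """Proposed substrates (in proposal order), their pool rows, and the
    GP state fitted on the real observations for this batch."""

    proposals: list[Substrate]
    indices: list[int]
    state: GPState


def propose_batch(
    b: int,
    pool: Sequence[Substrate],
    X_pool: np.ndarray,
    observations: Sequence[tuple[Substrate, float]],
    excluded: Set[Substrate] = frozenset(),
    gp_config: GPConfig = GPConfig(),
    acq_config: AcquisitionConfig = AcquisitionConfig(),
    seed: int = 0,
    f_best_raw: float | None = None,
    kriging_believer: bool = True,
    exclude_proposed: bool = True,
    warm_start: tuple[float, float, float] | None = None,
    n_restarts: int | None = None,
) -> BatchResult:
    """Propose ``b`` distinct substrates by iterated EI with fantasy updates.

    Parameters
    ----------
    observations
        Real (substrate, raw kJ/mol value) pairs — experimental and
        computational pooled with equal weight.  Outputs are standardized
        here; the fitted transform also maps ``f_best_raw``.
    f_best_raw
        Incumbent on the raw scale (default: the minimum observed value).
    kriging_believer, exclude_proposed
        Ablation switches.  With both disabled the same argmax is returned
        ``b`` times — a negative control for the fantasy mechanism.
    """
    if b < 1:
        raise ValueError(f"batch size must be >= 1, got {b}")
    pool_index = {s: i for i, s in enumerate(pool)}
    obs_rows = np.array([pool_index[s] for s, _ in observations])
    y_raw = np.array([v for _, v in observations], dtype=float)
    y_std, transform = standardize(y_raw)

    state = fit_hyperparameters(
        X_pool[obs_rows],
        y_std,
        config=gp_config,
        seed=seed,
        transform=transform,
        warm_start=warm_start,
        n_restarts=n_restarts,
    )
    f_best = float(
        transform.apply(np.min(y_raw) if f_best_raw is None else f_best_raw)
    )

    theta1, theta2, noise = state.theta1, state.theta2, state.noise_var
    n0 = len(obs_rows)
    N = len(pool)
    L0, _ = state._factor()

    # V[t] = L^-1 k(x_t, pool); grows by one row per fantasy point
    V = np.empty((n0 + max(b - 1, 0), N))
    Ks = kernel_matrix(X_pool[obs_rows], X_pool, theta1, theta2)  # (n0, N)
    V[:n0] = linalg.solve_triangular(L0, Ks, lower=True, check_finite=False)
    w = linalg.solve_triangular(L0, y_std, lower=True, check_finite=False)
    w = np.concatenate([w, np.zeros(max(b - 1, 0))])

    mean = V[:n0].T @ w[:n0]
    var = np.maximum(theta1 - np.einsum("ij,ij->j", V[:n0], V[:n0]), 0.0)

    eligible = np.array([s not in excluded for s in pool], dtype=bool)
    proposals: list[Substrate] = []
    indices: list[int] = []
    n = n0
    for t in range(b):
        if not eligible.any():
            raise PartialBatchError(
                f"eligible pool exhausted after {len(proposals)} of {b} proposals",
                proposals,
            )
        ei = np.asarray(expected_improvement(mean, var, f_best, acq_config))
        ei = np.where(eligible, ei, -np.inf)
        j = int(np.argmax(ei))
        proposals.append(pool[j])
        indices.append(j)
        if exclude_proposed:
            eligible[j] = False
        if kriging_believer and t < b - 1:
            v_new = V[:n, j].copy()
            d2 = theta1 + noise - float(v_new @ v_new)
            d = float(np.sqrt(max(d2, 1e-12)))
            y_fantasy = mean[j]  # believer value: the current posterior mean
            w[n] = (y_fantasy - float(v_new @ w[:n])) / d
            kvec = kernel_matrix(X_pool[j], X_pool, theta1, theta2)[0]
            r = (kvec - V[:n].T @ v_new) / d
            V[n] = r
            mean = mean + r * w[n]
            var = np.maximum(var - r * r, 0.0)
            n += 1
    return BatchResult(proposals=proposals, indices=indices, state=state)
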