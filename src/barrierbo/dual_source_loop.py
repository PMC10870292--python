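"""Alternating experiment/computation Bayesian-optimization loop.

Each cycle (i) evaluates a batch of ``n`` substrates with the exact
"experiment" oracle (the first batch is uniform random, later batches are
model-proposed), (ii) fits a GP on all experimental plus computational data
pooled with equal weight and proposes ``m`` substrates for the cheap
"computation" oracle — the exact barrier corrupted by Gaussian noise
``eps ~ N(mu, sigma^2)`` representing a method's systematic deviation and
random scatter — and (iii) proposes the next experimental batch.  The loop
stops once the experimental budget is spent.

Exclusion is asymmetric: a substrate is never *experimented* twice, and
computation proposals avoid everything already experimented or computed, but
a computed substrate may later be promoted to an experiment.  Computational
values are never corrected for ``mu``; the GP is left to absorb the offset.

One master seed derives independent substreams for the initial batch, the
noise draws, and the hyperparameter restarts, so noise realizations are
comparable across ``m`` settings with shared seeds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from .acquisition import AcquisitionConfig
from .batch_proposal import PartialBatchError, propose_batch
from .gp_core import GPConfig, feature_standardize
from .substrate_space import (
    BarrierLandscape,
    DatasetError,
    DescriptorTable,
    Substrate,
    encode_all,
)


class LoopError(ValueError):
    pass


@dataclass(frozen=True)
class NoiseModel:
    """Gaussian corruption of the computation oracle: eps ~ N(mu, sigma^2).

    ``mu`` (kJ/mol) is the systematic over/underestimation of barriers by the
    emulated computational method; ``sigma`` (kJ/mol) its unstructured error.
    """

    mu: float = 0.0
    sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise LoopError(f"sigma must be >= 0, got {self.sigma}")


def virtual_experiment(s: Substrate, landscape: BarrierLandscape) -> float:
    """Exact oracle: the stored barrier, no noise."""
    return landscape.barrier(s)


def virtual_computation(
    s: Substrate,
    landscape: BarrierLandscape,
    noise: NoiseModel,
    rng: np.random.Generator,
) -> float:
    """Noisy oracle: barrier + eps, one draw consumed from ``rng`` per call."""
    eps = float(rng.normal(noise.mu, noise.sigma))
    return landscape.barrier(s) + eps


@dataclass(frozen=True)
class LoopConfig:
    """Loop behavior not covered by (n, m, budget, noise).

    ``skip_final_computation``: the last cycle's computations can no longer
    inform any experiment, so they are skipped by default.
    ``f_best_source``: which observations define the EI incumbent —
    ``"experimental"`` (default: only verified outcomes) or ``"pooled"``.
    ``warm_start_restarts``: hyperparameter restarts for refits after the
    first (warm-started from the previous optimum).
    """

    skip_final_computation: bool = True
    f_best_source: str = "experimental"
    warm_start_restarts: int = 1

    def __post_init__(self) -> None:
        if self.f_best_source not in ("experimental", "pooled"):
            raise LoopError(f"unknown f_best_source: {self.f_best_source!r}")


@dataclass
class RunRecord:
    """Full trace of one optimization run.

    ``experimental`` and ``computational`` are ordered (substrate, value)
    lists; ``*_batch_ends`` give the cumulative lengths at each batch
    boundary.  ``truncated`` flags pool exhaustion mid-run.
    """

    experimental: list[tuple[Substrate, float]]
    computational: list[tuple[Substrate, float]]
    experimental_batch_ends: list[int]
    computational_batch_ends: list[int]
    seed: int
    config: dict[str, Any] = field(default_factory=dict)
    truncated: bool = False

    @property
    def n_batches(self) -> int:
        return len(self.experimental_batch_ends)

    def experimental_batch(self, b: int) -> list[tuple[Substrate, float]]:
        """The (1-based) b-th experimental batch."""
        ends = [0] + self.experimental_batch_ends
        return self.experimental[ends[b - 1] : ends[b]]

    def best_experimental(self) -> tuple[Substrate, float]:
        return min(self.experimental, key=lambda sv: (sv[1], sv[0]))

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "experimental": [[list(s), v] for s, v in self.experimental],
            "computational": [[list(s), v] for s, v in self.computational],
            "experimental_batch_ends": self.experimental_batch_ends,
            "computational_batch_ends": self.computational_batch_ends,
            "seed": self.seed,
            "config": self.config,
            "truncated": self.truncated,
        }
        text = json.dumps(payload)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "RunRecord":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = json.loads(text)
        return cls(
            experimental=[(tuple(s), v) for s, v in d["experimental"]],
            computational=[(tuple(s), v) for s, v in d["computational"]],
            experimental_batch_ends=d["experimental_batch_ends"],
            computational_batch_ends=d["computational_batch_ends"],
            seed=d["seed"],
            config=d["config"],
            truncated=d["truncated"],
        )


def run_optimization(
    landscape: BarrierLandscape,
    table: DescriptorTable,
    n: int,
    m: int,
    noise: NoiseModel,
    budget: int,
    seed: int,
    gp_config: GPConfig = GPConfig(),
    acq_config: AcquisitionConfig = AcquisitionConfig(),
    loop_config: LoopConfig = LoopConfig(),
) -> RunRecord:
    """Run the full dual-source loop until ``budget`` experiments are spent.

    ``budget`` must be a multiple of ``n``; the pool must accommodate at
    least ``n + m`` substrates.  Deterministic given ``seed`` and the
    configuration.  On pool exhaustion a truncated record is returned with
    ``truncated=True``.
    """
    if n < 1:
        raise LoopError(f"n must be >= 1, got {n}")
    if m < 0:
        raise LoopError(f"m must be >= 0, got {m}")
    if budget % n != 0 or budget < n:
        raise LoopError(f"budget ({budget}) must be a positive multiple of n ({n})")
    if landscape.n_missing:
        raise DatasetError("landscape must be fully imputed before optimization")
    if n + m > len(landscape):
        raise LoopError(f"pool of {len(landscape)} cannot host n + m = {n + m}")

    # lexicographic pool order fixes all tie-breaks
    order = sorted(range(len(landscape)), key=lambda i: landscape.substrates[i])
    pool: list[Substrate] = [landscape.substrates[i] for i in order]
    X_pool = feature_standardize(encode_all(pool, table))

    ss_init, ss_noise, ss_fit = np.random.SeedSequence(seed).spawn(3)
    rng_init = np.random.default_rng(ss_init)
    rng_noise = np.random.default_rng(ss_noise)
    rng_fit = np.random.default_rng(ss_fit)

    config_snapshot = {
        "n": n,
        "m": m,
        "mu": noise.mu,
        "sigma": noise.sigma,
        "budget": budget,
        "xi": acq_config.xi,
        "skip_final_computation": loop_config.skip_final_computation,
        "f_best_source": loop_config.f_best_source,
        "n_substrates": len(pool),
    }

    experimental: list[tuple[Substrate, float]] = []
    computational: list[tuple[Substrate, float]] = []
    exp_ends: list[int] = []
    comp_ends: list[int] = []
    exp_set: set[Substrate] = set()
    comp_set: set[Substrate] = set()
    warm: tuple[float, float, float] | None = None
    truncated = False

    def f_best_raw() -> float:
        if loop_config.f_best_source == "pooled" and computational:
            return min(
                min(v for _, v in experimental), min(v for _, v in computational)
            )
        return min(v for _, v in experimental)

    def fit_seed() -> int:
        return int(rng_fit.integers(2**31))

    n_cycles = budget // n
    first_rows = rng_init.choice(len(pool), size=n, replace=False)
    pending: list[Substrate] = [pool[i] for i in sorted(first_rows)]

    for cycle in range(1, n_cycles + 1):
        for s in pending:
            experimental.append((s, virtual_experiment(s, landscape)))
            exp_set.add(s)
        exp_ends.append(len(experimental))
        last = cycle == n_cycles

        restarts = None if cycle == 1 else loop_config.warm_start_restarts
        if m > 0 and (not last or not loop_config.skip_final_computation):
            try:
                res = propose_batch(
                    m,
                    pool,
                    X_pool,
                    experimental + computational,
                    excluded=exp_set | comp_set,
                    gp_config=gp_config,
                    acq_config=acq_config,
                    seed=fit_seed(),
                    f_best_raw=f_best_raw(),
                    warm_start=warm,
                    n_restarts=restarts,
                )
            except PartialBatchError:
                truncated = True
                break
            warm = (res.state.theta1, res.state.theta2, res.state.noise_var)
            for s in res.proposals:
                computational.append(
                    (s, virtual_computation(s, landscape, noise, rng_noise))
                )
                comp_set.add(s)
            comp_ends.append(len(computational))
            restarts = loop_config.warm_start_restarts

        if not last:
            try:
                res = propose_batch(
                    n,
                    pool,
                    X_pool,
                    experimental + computational,
                    excluded=set(exp_set),
                    gp_config=gp_config,
                    acq_config=acq_config,
                    seed=fit_seed(),
                    f_best_raw=f_best_raw(),
                    warm_start=warm,
                    n_restarts=restarts,
                )
            except PartialBatchError:
                truncated = True
                break
            warm = (res.state.theta1, res.state.theta2, res.state.noise_var)
            pending = res.proposals

    return RunRecord(
        experimental=experimental,
        computational=computational,
        experimental_batch_ends=exp_ends,
        computational_batch_ends=comp_ends,
        seed=seed,
        config=config_snapshot,
        truncated=truncated,
    )
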