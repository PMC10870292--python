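"""Benchmarking protocol: repeated seeded runs over an (m, mu, sigma) grid.

Performance is measured as the *top-k success rate*: the fraction of repeated
runs in which at least one of the ``k`` lowest-barrier substrates has been
experimentally evaluated by a given batch.  Per-run success indicators are
monotone step functions of the batch index; averaging them over runs gives
the success curve for one grid point, and the first batch at which the
averaged curve crosses a threshold gives the experiments-to-threshold
summary (the heatmap quantity).

Runs are paired across grid points: repetition ``r`` uses seed
``base_seed + r`` everywhere, so the initial batches coincide and grid
points can be compared with paired statistics.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .acquisition import AcquisitionConfig
from .dual_source_loop import LoopConfig, NoiseModel, RunRecord, run_optimization
from .gp_core import GPConfig
from .substrate_space import BarrierLandscape, DescriptorTable, Substrate

logger = logging.getLogger(__name__)

NOT_REACHED = "not_reached"

# paper-scale grid shape; desk runs override repetitions and the landscape
DEFAULT_M_VALUES = (5, 10, 15, 20, 25, 30)
DEFAULT_MU_VALUES = (-20.0, -10.0, 0.0, 10.0, 20.0)
DEFAULT_SIGMA_VALUES = (0.0, 5.0, 10.0, 15.0, 20.0)


@dataclass(frozen=True)
class BenchmarkConfig:
    """Grid and protocol parameters for a benchmark campaign."""

    m_values: tuple[int, ...] = DEFAULT_M_VALUES
    mu_values: tuple[float, ...] = DEFAULT_MU_VALUES
    sigma_values: tuple[float, ...] = DEFAULT_SIGMA_VALUES
    repetitions: int = 200
    n_per_batch: int = 5
    budget: int = 100
    success_set_size: int = 10
    success_threshold: float = 0.95
    base_seed: int = 0
    include_reference: bool = True  # schedule the m = 0 baseline row

    def __post_init__(self) -> None:
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        if self.success_set_size < 1:
            raise ValueError("success_set_size must be >= 1")
        if not (0 < self.success_threshold <= 1):
            raise ValueError("success_threshold must be in (0, 1]")


def planned_run_count(cfg: BenchmarkConfig) -> dict[str, int]:
    """Dry-run scheduler tally: how many runs a campaign would execute.

    ``noisy`` counts the m > 0 grid; ``reference`` the m = 0 baseline
    repetitions; ``total`` their sum.  No runs are executed.
    """
    noisy = (
        len(cfg.m_values) * len(cfg.mu_values) * len(cfg.sigma_values) * cfg.repetitions
    )
    reference = cfg.repetitions if cfg.include_reference else 0
    return {"noisy": noisy, "reference": reference, "total": noisy + reference}


def success_indicator(record: RunRecord, top_set: set[Substrate]) -> np.ndarray:
    """Per-batch success: has any top-set member been *experimented* yet?

    Computational evaluations never count.  The result is a boolean vector
    over experimental batches, monotone non-decreasing.
    """
    if not top_set:
        raise ValueError("top_set is empty")
    if not record.experimental_batch_ends:
        raise ValueError("record has no experimental batches")
    hits = np.array([s in top_set for s, _ in record.experimental], dtype=bool)
    cum = np.cumsum(hits) > 0
    ends = np.asarray(record.experimental_batch_ends, dtype=int)
    return cum[ends - 1]


@dataclass
class SuccessCurve:
    """Averaged success curve at one grid point, plus per-run first successes.

    ``first_success_batch`` holds the 1-based batch of first success per run,
    or +inf when the run never succeeded within budget.
    """

    rates: np.ndarray
    first_success_batch: np.ndarray

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        self.first_success_batch = np.asarray(self.first_success_batch, dtype=float)
        if np.any(np.diff(self.rates) < -1e-12):
            raise ValueError("success curve must be monotone non-decreasing")

    @property
    def n_runs(self) -> int:
        return self.first_success_batch.size

    @property
    def final_rate(self) -> float:
        return float(self.rates[-1])

    @classmethod
    def from_indicators(cls, indicators: np.ndarray) -> "SuccessCurve":
        """Build from an (n_runs, n_batches) boolean indicator matrix."""
        ind = np.atleast_2d(np.asarray(indicators, dtype=bool))
        rates = ind.mean(axis=0)
        first = np.full(ind.shape[0], np.inf)
        any_hit = ind.any(axis=1)
        first[any_hit] = ind[any_hit].argmax(axis=1) + 1
        return cls(rates=rates, first_success_batch=first)


def experiments_to_threshold(
    curve: SuccessCurve, n_per_batch: int, threshold: float
) -> int | str:
    """Experiments needed for the averaged curve to reach ``threshold``.

    Returns ``n_per_batch * (first qualifying batch)`` or the
    :data:`NOT_REACHED` sentinel when the curve never reaches it.
    """
    qualifying = np.nonzero(curve.rates >= threshold)[0]
    if qualifying.size == 0:
        return NOT_REACHED
    return int(n_per_batch * (qualifying[0] + 1))


@dataclass
class BenchmarkResult:
    """Curves keyed by (m, mu, sigma); the m = 0 reference key is (0, 0.0, 0.0)."""

    curves: dict[tuple[int, float, float], SuccessCurve]
    config: BenchmarkConfig
    failures: list[tuple[int, float, float]] = field(default_factory=list)

    def aggregate_frame(self) -> pd.DataFrame:
        rows = []
        for (m, mu, sigma), curve in sorted(self.curves.items()):
            for b, rate in enumerate(curve.rates, start=1):
                rows.append(
                    {
                        "m": m,
                        "mu_kj_mol": mu,
                        "sigma_kj_mol": sigma,
                        "batch": b,
                        "success_rate": rate,
                        "n_runs": curve.n_runs,
                    }
                )
        return pd.DataFrame(rows)

    def first_success_frame(self) -> pd.DataFrame:
        rows = []
        for (m, mu, sigma), curve in sorted(self.curves.items()):
            for r, fb in enumerate(curve.first_success_batch):
                rows.append(
                    {
                        "m": m,
                        "mu_kj_mol": mu,
                        "sigma_kj_mol": sigma,
                        "run": r,
                        "seed": self.config.base_seed + r,
                        "first_success_batch": NOT_REACHED if np.isinf(fb) else int(fb),
                    }
                )
        return pd.DataFrame(rows)

    def heatmap_frame(self, threshold: float | None = None) -> pd.DataFrame:
        """Experiments-to-threshold per grid point (the heatmap table)."""
        thr = self.config.success_threshold if threshold is None else threshold
        rows = []
        for (m, mu, sigma), curve in sorted(self.curves.items()):
            rows.append(
                {
                    "m": m,
                    "mu_kj_mol": mu,
                    "sigma_kj_mol": sigma,
                    "experiments_to_threshold": experiments_to_threshold(
                        curve, self.config.n_per_batch, thr
                    ),
                }
            )
        return pd.DataFrame(rows)


def run_grid(
    cfg: BenchmarkConfig,
    landscape: BarrierLandscape,
    table: DescriptorTable,
    gp_config: GPConfig = GPConfig(),
    acq_config: AcquisitionConfig = AcquisitionConfig(),
    loop_config: LoopConfig = LoopConfig(),
    progress: bool = False,
) -> BenchmarkResult:
    """Execute the full campaign and aggregate success curves.

    Repetition ``r`` of every grid point uses seed ``base_seed + r`` so grid
    points are comparable pairwise.  A failed run aborts its grid point (it
    is listed in ``failures``) and the remaining points proceed.
    """
    top_set = set(landscape.top_set(cfg.success_set_size))
    points: list[tuple[int, float, float]] = []
    if cfg.include_reference:
        points.append((0, 0.0, 0.0))
    points.extend(
        (m, mu, sigma)
        for m, mu, sigma in itertools.product(
            cfg.m_values, cfg.mu_values, cfg.sigma_values
        )
    )

    curves: dict[tuple[int, float, float], SuccessCurve] = {}
    failures: list[tuple[int, float, float]] = []
    for m, mu, sigma in points:
        indicators = []
        try:
            for r in range(cfg.repetitions):
                record = run_optimization(
                    landscape,
                    table,
                    n=cfg.n_per_batch,
                    m=m,
                    noise=NoiseModel(mu=mu, sigma=sigma),
                    budget=cfg.budget,
                    seed=cfg.base_seed + r,
                    gp_config=gp_config,
                    acq_config=acq_config,
                    loop_config=loop_config,
                )
                indicators.append(success_indicator(record, top_set))
            curves[(m, mu, sigma)] = SuccessCurve.from_indicators(np.array(indicators))
            if progress:
                logger.info(
                    "grid point m=%d mu=%.1f sigma=%.1f: final rate %.3f",
                    m, mu, sigma, curves[(m, mu, sigma)].final_rate,
                )
        except Exception:
            logger.exception(
                "grid point m=%d mu=%.1f sigma=%.1f failed; skipping", m, mu, sigma
            )
            failures.append((m, mu, sigma))
    return BenchmarkResult(curves=curves, config=cfg, failures=failures)


def plot_success_curves(result: BenchmarkResult, path: str | Path) -> None:
    """One panel per (mu, sigma) with a line per m, mirroring the usual
    success-curve figure layout.  Requires matplotlib."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mus = sorted({k[1] for k in result.curves if k[0] != 0})
    sigmas = sorted({k[2] for k in result.curves if k[0] != 0})
    if not mus:
        mus, sigmas = [0.0], [0.0]
    fig, axes = plt.subplots(
        len(mus), len(sigmas), figsize=(3 * len(sigmas), 2.5 * len(mus)),
        squeeze=False, sharex=True, sharey=True,
    )
    ref = result.curves.get((0, 0.0, 0.0))
    for i, mu in enumerate(mus):
        for j, sigma in enumerate(sigmas):
            ax = axes[i][j]
            if ref is not None:
                ax.plot(range(1, len(ref.rates) + 1), ref.rates, "k--", label="m=0")
            for (m, mu_k, sigma_k), curve in sorted(result.curves.items()):
                if m != 0 and mu_k == mu and sigma_k == sigma:
                    ax.plot(range(1, len(curve.rates) + 1), curve.rates, label=f"m={m}")
            ax.set_title(f"mu={mu:g}, sigma={sigma:g} kJ/mol", fontsize=8)
            ax.set_ylim(0, 1)
    axes[-1][0].set_xlabel("batch")
    axes[-1][0].set_ylabel("success rate")
    axes[0][0].legend(fontsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_heatmaps(result: BenchmarkResult, path: str | Path) -> None:
    """Experiments-to-threshold heatmaps, one panel per m."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = result.heatmap_frame()
    df = df[df["m"] != 0]
    ms = sorted(df["m"].unique())
    fig, axes = plt.subplots(1, max(len(ms), 1), figsize=(3.2 * max(len(ms), 1), 3), squeeze=False)
    budget = result.config.budget
    for ax, m in zip(axes[0], ms):
        sub = df[df["m"] == m].copy()
        sub["value"] = [
            budget * 2 if v == NOT_REACHED else v
            for v in sub["experiments_to_threshold"]
        ]
        pivot = sub.pivot(index="mu_kj_mol", columns="sigma_kj_mol", values="value")
        im = ax.imshow(pivot.to_numpy(), cmap="coolwarm", aspect="auto")
        ax.set_xticks(range(len(pivot.columns)), [f"{c:g}" for c in pivot.columns])
        ax.set_yticks(range(len(pivot.index)), [f"{r:g}" for r in pivot.index])
        ax.set_xlabel("sigma (kJ/mol)")
        ax.set_ylabel("mu (kJ/mol)")
        ax.set_title(f"m={m}")
        fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
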