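"""Synthetic Claisen-like barrier landscapes and descriptor tables.

The generator emulates the statistical structure a semiempirical barrier
dataset over a combinatorially substituted scaffold is expected to have:

* a base barrier with per-site additive substituent effects that are *linear
  functions of the substituent descriptors* (so descriptor-based regression
  can learn them),
* pairwise site-site interaction effects (epistasis) drawn as seeded
  Gaussians, and
* a per-substrate Gaussian residual,

all in kJ/mol.  With interaction and residual scales at zero the landscape is
exactly linear in the encoded descriptor vector; as they grow, an increasing
share of the barrier variance is invisible to any descriptor-based model,
which is what makes top-k identification genuinely hard.

The default :class:`LandscapeSpec` (4 sites x 8 substituents, 4,096
substrates) is a desk-scale stand-in for the ~100,000-substrate reaction
space used at cluster scale; ``LandscapeSpec(n_sites=5, n_substituents=10)``
reproduces the full combinatorics.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Any

import numpy as np
import pandas as pd

from .substrate_space import (
    BarrierLandscape,
    DescriptorTable,
    PARAM_COLUMNS,
    SpaceError,
    enumerate_substrates,
)

# Plausible ranges (uniform draws) for each substituent parameter. HOMO/LUMO
# in eV, NBO charge in e, Hammett dimensionless, Sterimol in Angstrom; all
# are treated as unitless features downstream.
_PARAM_RANGES: dict[str, tuple[float, float]] = {
    "homo": (-11.0, -8.0),
    "lumo": (-2.0, 3.0),
    "nbo_charge": (-0.6, 0.6),
    "hammett": (-0.4, 0.8),
    "sterimol_L": (2.0, 7.0),
    "sterimol_B1": (1.0, 3.5),
    "sterimol_B5": (1.5, 7.0),
}


@dataclass(frozen=True)
class LandscapeSpec:
    """Generative parameters of a synthetic barrier landscape.

    ``site_effect_scale`` is the standard deviation (over substituents) of
    each site's additive, descriptor-linked contribution; ``interaction_scale``
    the sd of each pairwise site-site effect; ``residual_scale`` the sd of the
    unstructured per-substrate residual.  All in kJ/mol.
    """

    n_sites: int = 4
    n_substituents: int = 8
    base_barrier: float = 120.0
    site_effect_scale: float = 6.0
    interaction_scale: float = 5.0
    residual_scale: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise SpaceError(f"n_sites must be >= 1, got {self.n_sites}")
        if self.n_substituents < 2:
            raise SpaceError(
                f"n_substituents must be >= 2, got {self.n_substituents}"
            )
        for name in ("site_effect_scale", "interaction_scale", "residual_scale"):
            if getattr(self, name) < 0:
                raise SpaceError(f"{name} must be >= 0")

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "LandscapeSpec":
        return cls(**d)


def _substituent_ids(k: int) -> list[str]:
    width = max(2, len(str(k)))
    return [f"R{i + 1:0{width}d}" for i in range(k)]


def generate_descriptor_table(spec: LandscapeSpec) -> DescriptorTable:
    """Draw a K x 8 descriptor table from fixed per-parameter ranges.

    HOMO-LUMO gap is derived as ``lumo - homo`` so the three orbital columns
    stay physically consistent.  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xD15C]))
    k = spec.n_substituents
    cols: dict[str, np.ndarray] = {}
    for name in PARAM_COLUMNS:
        if name == "gap":
            continue
        lo, hi = _PARAM_RANGES[name]
        cols[name] = rng.uniform(lo, hi, size=k)
    cols["gap"] = cols["lumo"] - cols["homo"]
    df = pd.DataFrame(cols, index=pd.Index(_substituent_ids(k), name="substituent_id"))
    return DescriptorTable(df[list(PARAM_COLUMNS)])


def site_effects(spec: LandscapeSpec, table: DescriptorTable) -> np.ndarray:
    """Per-site additive substituent effects, shape (n_sites, K), kJ/mol.

    Each site's effect is a random linear functional of the standardized
    descriptors, rescaled to have population sd ``site_effect_scale`` and
    mean 0 over the K substituents.  This ties the landscape to the
    descriptors: a model that reads them can predict these terms.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xA0]))
    params = table.data.to_numpy(dtype=float)  # (K, 8)
    mu = params.mean(axis=0)
    sd = params.std(axis=0)
    sd[sd == 0] = 1.0
    z = (params - mu) / sd
    effects = np.empty((spec.n_sites, spec.n_substituents))
    for site in range(spec.n_sites):
        w = rng.normal(size=z.shape[1])
        raw = z @ w
        spread = raw.std()
        if spread == 0:  # degenerate table; keep effect flat
            effects[site] = 0.0
        else:
            effects[site] = spec.site_effect_scale * (raw - raw.mean()) / spread
    return effects


def generate_landscape(spec: LandscapeSpec, table: DescriptorTable) -> BarrierLandscape:
    """Generate the full barrier landscape over the enumerated space.

    barrier(s) = base + sum_site a(site, s[site])
               + sum_{site pairs} b(pair, s[i], s[j]) + residual(s)

    where ``a`` comes from :func:`site_effects`, ``b`` are iid
    N(0, interaction_scale^2) draws per (site pair, substituent pair), and the
    residual is iid N(0, residual_scale^2) per substrate.  Deterministic given
    ``spec.seed``; covers all K^S substrates in lexicographic order.
    """
    if len(table.substituents) != spec.n_substituents:
        raise SpaceError(
            f"descriptor table has {len(table.substituents)} substituents, "
            f"spec expects {spec.n_substituents}"
        )
    subs = table.substituents
    substrates = enumerate_substrates(spec.n_sites, subs)
    k, s = spec.n_substituents, spec.n_sites
    n = len(substrates)

    # index array: substrate -> substituent index per site, lexicographic order
    idx = np.array(
        np.meshgrid(*[np.arange(k)] * s, indexing="ij")
    ).reshape(s, n).T  # (N, S)

    a = site_effects(spec, table)
    barriers = np.full(n, spec.base_barrier)
    for site in range(s):
        barriers += a[site, idx[:, site]]

    rng_b = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xB1]))
    for i in range(s):
        for j in range(i + 1, s):
            b = rng_b.normal(scale=spec.interaction_scale, size=(k, k))
            barriers += b[idx[:, i], idx[:, j]]

    rng_res = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xE5]))
    barriers += rng_res.normal(scale=spec.residual_scale, size=n)
    return BarrierLandscape(substrates, barriers)


def generate(spec: LandscapeSpec) -> tuple[DescriptorTable, BarrierLandscape]:
    """Convenience: descriptor table and landscape from one spec."""
    table = generate_descriptor_table(spec)
    return table, generate_landscape(spec, table)
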