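"""Combinatorial substrate space, descriptor encoding, and barrier-dataset I/O.

A *substrate* is an assignment of one substituent to each of ``n_sites``
substitution sites on a common scaffold, represented as an ordered tuple of
substituent ids.  Each substituent carries eight electronic and steric
parameters (HOMO energy, LUMO energy, HOMO-LUMO gap, NBO charge, Hammett
constant and the Sterimol L/B1/B5 parameters); a substrate is encoded for
regression as the site-by-site concatenation of these parameters, giving a
fixed-length vector of ``8 * n_sites`` features.

The *barrier landscape* maps every substrate in the enumerated space to a
Gibbs energy barrier in kJ/mol and serves as the exact "virtual experiment"
oracle downstream.  Landscapes loaded from CSV may contain missing barriers;
:func:`impute_missing` fills them by regression on the descriptor encoding.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The eight per-substituent descriptor columns, in canonical order.
PARAM_COLUMNS = (
    "homo",
    "lumo",
    "gap",
    "nbo_charge",
    "hammett",
    "sterimol_L",
    "sterimol_B1",
    "sterimol_B5",
)

N_PARAMS = len(PARAM_COLUMNS)

#: A substrate: ordered tuple of substituent ids, one per site.
Substrate = tuple[str, ...]


class SpaceError(ValueError):
    """Invalid configuration of the combinatorial space."""


class DatasetError(ValueError):
    """Malformed barrier dataset or descriptor table."""


@dataclass(frozen=True)
class DescriptorTable:
    """Eight numeric parameters per substituent.

    Parameters
    ----------
    data
        DataFrame indexed by substituent id with exactly the columns in
        :data:`PARAM_COLUMNS`.  All values must be finite and the index
        must be unique.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in PARAM_COLUMNS if c not in df.columns]
        if missing:
            raise DatasetError(f"descriptor table missing columns: {missing}")
        if not df.index.is_unique:
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise DatasetError(f"duplicate substituent ids: {dupes}")
        values = df[list(PARAM_COLUMNS)].to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            raise DatasetError("descriptor table contains non-finite values")
        object.__setattr__(self, "data", df[list(PARAM_COLUMNS)].astype(float))

    @property
    def substituents(self) -> list[str]:
        return list(self.data.index)

    def vector(self, substituent_id: str) -> np.ndarray:
        """The 8-parameter descriptor vector of one substituent."""
        try:
            return self.data.loc[substituent_id].to_numpy(dtype=float)
        except KeyError:
            raise DatasetError(f"unknown substituent id: {substituent_id!r}") from None

    @classmethod
    def from_csv(cls, path: str | Path) -> "DescriptorTable":
        df = pd.read_csv(path)
        if "substituent_id" not in df.columns:
            raise DatasetError("descriptor CSV must have a 'substituent_id' column")
        return cls(df.set_index("substituent_id"))

    def to_csv(self, path: str | Path) -> None:
        self.data.rename_axis("substituent_id").to_csv(path)


@dataclass
class BarrierLandscape:
    """Complete map substrate -> Gibbs energy barrier (kJ/mol).

    Substrates are stored in a fixed (normally lexicographic) order; barriers
    are a parallel float array with NaN marking missing values.
    """

    substrates: list[Substrate]
    barriers: np.ndarray  # shape (len(substrates),), NaN = missing
    _index: dict[Substrate, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.barriers = np.asarray(self.barriers, dtype=float)
        if self.barriers.shape != (len(self.substrates),):
            raise DatasetError("barrier array length does not match substrate list")
        self._index = {s: i for i, s in enumerate(self.substrates)}
        if len(self._index) != len(self.substrates):
            raise DatasetError("duplicate substrates in landscape")

    def __len__(self) -> int:
        return len(self.substrates)

    def __contains__(self, s: Substrate) -> bool:
        return s in self._index

    def index_of(self, s: Substrate) -> int:
        try:
            return self._index[s]
        except KeyError:
            raise DatasetError(f"substrate not in landscape: {s}") from None

    def barrier(self, s: Substrate) -> float:
        return float(self.barriers[self.index_of(s)])

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.barriers).sum())

    @property
    def n_sites(self) -> int:
        return len(self.substrates[0]) if self.substrates else 0

    def top_set(self, k: int) -> list[Substrate]:
        """The ``k`` substrates with the lowest barriers.

        Ties are broken by the stored (lexicographic) substrate order, so the
        set is stable across recomputation.
        """
        if self.n_missing:
            raise DatasetError("top_set requires a fully imputed landscape")
        order = np.argsort(self.barriers, kind="stable")
        return [self.substrates[i] for i in order[:k]]

    def to_csv(self, path: str | Path) -> None:
        n_sites = self.n_sites
        cols = {f"site_{i + 1}": [s[i] for s in self.substrates] for i in range(n_sites)}
        df = pd.DataFrame(cols)
        df["barrier_kj_mol"] = self.barriers
        df.to_csv(path, index=False)


def enumerate_substrates(n_sites: int, substituents: Sequence[str]) -> list[Substrate]:
    """All ``K**S`` substituent assignments, in lexicographic order.

    The order is lexicographic in the *given* substituent sequence: the first
    site varies slowest.  Raises :class:`SpaceError` on an empty substituent
    list or non-positive site count.
    """
    if n_sites < 1:
        raise SpaceError(f"n_sites must be >= 1, got {n_sites}")
    subs = list(substituents)
    if not subs:
        raise SpaceError("substituent list is empty")
    if len(set(subs)) != len(subs):
        raise SpaceError("substituent ids must be unique")
    return [tuple(p) for p in itertools.product(subs, repeat=n_sites)]


def encode_descriptors(s: Substrate, table: DescriptorTable) -> np.ndarray:
    """Encode a substrate as the concatenation of its substituents' parameters.

    Site order follows the substrate tuple (dataset column order); the result
    has length ``8 * n_sites``.
    """
    parts = []
    for site, sub_id in enumerate(s):
        try:
            parts.append(table.data.loc[sub_id].to_numpy(dtype=float))
        except KeyError:
            raise DatasetError(
                f"unknown substituent id {sub_id!r} at site {site + 1}"
            ) from None
    return np.concatenate(parts)


def encode_all(substrates: Sequence[Substrate], table: DescriptorTable) -> np.ndarray:
    """Vectorized :func:`encode_descriptors` over a list of substrates.

    Returns an array of shape ``(len(substrates), 8 * n_sites)``.
    """
    if not substrates:
        return np.empty((0, 0))
    sub_ids = table.substituents
    pos = {sid: i for i, sid in enumerate(sub_ids)}
    params = table.data.to_numpy(dtype=float)  # (K, 8)
    n_sites = len(substrates[0])
    try:
        idx = np.array([[pos[sid] for sid in s] for s in substrates])  # (N, S)
    except KeyError as e:
        raise DatasetError(f"unknown substituent id {e.args[0]!r}") from None
    return params[idx].reshape(len(substrates), n_sites * N_PARAMS)


def load_barrier_dataset(path: str | Path) -> BarrierLandscape:
    """Read a barrier dataset CSV into a :class:`BarrierLandscape`.

    Expected columns: ``site_1 .. site_S`` (substituent ids) followed by
    ``barrier_kj_mol`` (float; empty cells mark missing values).  Duplicate
    substrate rows are an error.  Row and missing counts are logged.
    """
    df = pd.read_csv(path, dtype={"barrier_kj_mol": float}, float_precision="round_trip")
    site_cols = [c for c in df.columns if c.startswith("site_")]
    if not site_cols or "barrier_kj_mol" not in df.columns:
        raise DatasetError(
            f"{path}: expected site_1..site_S and barrier_kj_mol columns, "
            f"got {list(df.columns)}"
        )
    site_cols = sorted(site_cols, key=lambda c: int(c.split("_")[1]))
    if df[site_cols].isna().any().any():
        row = int(df[df[site_cols].isna().any(axis=1)].index[0])
        raise DatasetError(f"{path}: malformed row {row + 2}: empty site column")
    substrates = [tuple(str(v) for v in row) for row in df[site_cols].itertuples(index=False)]
    seen: dict[Substrate, int] = {}
    for i, s in enumerate(substrates):
        if s in seen:
            raise DatasetError(
                f"{path}: duplicate substrate {s} at rows {seen[s] + 2} and {i + 2}"
            )
        seen[s] = i
    barriers = df["barrier_kj_mol"].to_numpy(dtype=float)
    landscape = BarrierLandscape(substrates, barriers)
    logger.info(
        "loaded %d substrates from %s (%d missing barriers)",
        len(landscape), path, landscape.n_missing,
    )
    return landscape


@dataclass(frozen=True)
class ImputerConfig:
    """Regressor used to fill missing barriers.

    ``kind`` selects the model: ``"random_forest"`` (default) or ``"linear"``.
    The seed makes tree-ensemble imputation reproducible.
    """

    kind: str = "random_forest"
    n_estimators: int = 200
    seed: int = 0


def impute_missing(
    landscape: BarrierLandscape,
    table: DescriptorTable,
    config: ImputerConfig = ImputerConfig(),
) -> BarrierLandscape:
    """Fill missing barriers by regression on the descriptor encoding.

    Trains on (descriptor vector -> barrier) pairs from the observed entries
    and predicts each missing one.  Observed entries are returned unchanged
    (bitwise).  A landscape with no missing entries is returned as-is.
    """
    mask = np.isnan(landscape.barriers)
    if not mask.any():
        return landscape
    if mask.all():
        raise DatasetError("cannot impute: every barrier is missing")

    X = encode_all(landscape.substrates, table)
    if config.kind == "random_forest":
        from sklearn.ensemble import RandomForestRegressor

        model = RandomForestRegressor(
            n_estimators=config.n_estimators, random_state=config.seed
        )
    elif config.kind == "linear":
        from sklearn.linear_model import LinearRegression

        model = LinearRegression()
    else:
        raise DatasetError(f"unknown imputer kind: {config.kind!r}")

    model.fit(X[~mask], landscape.barriers[~mask])
    filled = landscape.barriers.copy()
    filled[mask] = model.predict(X[mask])
    logger.info("imputed %d missing barriers with %s", int(mask.sum()), config.kind)
    return BarrierLandscape(list(landscape.substrates), filled)
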