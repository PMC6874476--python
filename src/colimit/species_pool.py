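"""Species pools and global model configuration.

A pool describes ``S`` specialist microbial species competing for ``K``
carbon and ``M`` nitrogen metabolites in a chemostat. Each species consumes
exactly one carbon and one nitrogen source and is characterised by four
traits: competitive abilities ``lambda_c``, ``lambda_n`` (growth rate per
unit resource concentration) and growth yields ``yield_c``, ``yield_n``
(biomass produced per unit resource consumed). The ratio
``yield_n / yield_c`` is the species' C:N stoichiometry.

All enumeration and invadability logic downstream assumes a strict rank
order of competitive abilities within each resource column, so pools with
tied lambdas on a shared resource are rejected at construction time.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SpeciesTraits",
    "SpeciesPool",
    "ModelConfig",
    "PoolError",
    "generate_random_pool",
    "generate_equal_stoichiometry_pool",
    "load_pool",
    "save_pool",
    "competitiveness_ranks",
]

POOL_COLUMNS = ["species_id", "i", "j", "lambda_c", "lambda_n", "yield_c", "yield_n"]


class PoolError(ValueError):
    """Raised for invalid species pools or configuration."""


@dataclass(frozen=True)
class SpeciesTraits:
    """Traits of one specialist species.

    ``carbon_index`` / ``nitrogen_index`` are 1-based indices of the single
    carbon and nitrogen metabolite the species can use.
    """

    species_id: int
    carbon_index: int
    nitrogen_index: int
    lambda_c: float
    lambda_n: float
    yield_c: float
    yield_n: float

    def __post_init__(self) -> None:
        for name in ("lambda_c", "lambda_n", "yield_c", "yield_n"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise PoolError(
                    f"species {self.species_id}: {name}={v!r} must be finite and > 0"
                )
        if self.carbon_index < 1 or self.nitrogen_index < 1:
            raise PoolError(
                f"species {self.species_id}: resource indices are 1-based positive"
            )

    @property
    def stoichiometry(self) -> float:
        """C:N stoichiometry, the yield ratio Y(n)/Y(c)."""
        return self.yield_n / self.yield_c


@dataclass(frozen=True)
class SpeciesPool:
    """A pool of specialist species on K carbon and M nitrogen metabolites."""

    K: int
    M: int
    species: tuple[SpeciesTraits, ...]

    def __post_init__(self) -> None:
        if self.K < 1 or self.M < 1:
            raise PoolError("K and M must be >= 1")
        seen_ids: set[int] = set()
        for sp in self.species:
            if sp.carbon_index > self.K or sp.nitrogen_index > self.M:
                raise PoolError(
                    f"species {sp.species_id} uses resource outside the "
                    f"{self.K}C x {self.M}N grid"
                )
            if sp.species_id in seen_ids:
                raise PoolError(f"duplicate species_id {sp.species_id}")
            seen_ids.add(sp.species_id)
        # strict rank order within every resource column
        for i in range(1, self.K + 1):
            lams = [sp.lambda_c for sp in self.species if sp.carbon_index == i]
            if len(set(lams)) != len(lams):
                raise PoolError(
                    f"tie in competitive abilities lambda_c on carbon {i}"
                )
        for j in range(1, self.M + 1):
            lams = [sp.lambda_n for sp in self.species if sp.nitrogen_index == j]
            if len(set(lams)) != len(lams):
                raise PoolError(
                    f"tie in competitive abilities lambda_n on nitrogen {j}"
                )

    @property
    def S(self) -> int:
        return len(self.species)

    def by_id(self, species_id: int) -> SpeciesTraits:
        for sp in self.species:
            if sp.species_id == species_id:
                return sp
        raise KeyError(species_id)

    def carbon_consumers(self, i: int) -> list[SpeciesTraits]:
        return [sp for sp in self.species if sp.carbon_index == i]

    def nitrogen_consumers(self, j: int) -> list[SpeciesTraits]:
        return [sp for sp in self.species if sp.nitrogen_index == j]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (sp.species_id, sp.carbon_index, sp.nitrogen_index,
             sp.lambda_c, sp.lambda_n, sp.yield_c, sp.yield_n)
            for sp in self.species
        ]
        return pd.DataFrame(rows, columns=POOL_COLUMNS)

    def with_yields(
        self, yields: Mapping[int, tuple[float, float]]
    ) -> "SpeciesPool":
        """Return a pool with the same lambdas but new (yield_c, yield_n)."""
        new = tuple(
            replace(sp, yield_c=yields[sp.species_id][0],
                    yield_n=yields[sp.species_id][1])
            if sp.species_id in yields else sp
            for sp in self.species
        )
        return SpeciesPool(self.K, self.M, new)


@dataclass
class ModelConfig:
    """Global model and sampling configuration.

    The defaults put the system in the high-supply regime
    ``phi >> delta^2 / lambda``: with ``delta = 1`` and ``lambda >= 10``
    the largest ``delta^2/lambda`` is 0.1, far below ``supply_low = 10``,
    so invadability depends only on the rank order of competitive abilities
    and limiting-nutrient concentrations are negligible against abiotic
    ones.
    """

    delta: float = 1.0
    supply_low: float = 10.0
    supply_high: float = 1000.0
    n_samples: int = 100_000
    rng_seed: int = 0
    perturbation_magnitude: float = 0.01
    rtol: float = 1e-8
    atol: float = 1e-10
    extinction_threshold: float = 1e-9

    def validate(self, pool: SpeciesPool | None = None) -> None:
        if self.delta <= 0:
            raise PoolError("delta must be > 0")
        if not (0 < self.supply_low < self.supply_high):
            raise PoolError("need 0 < supply_low < supply_high")
        if pool is not None:
            lam_min = min(
                min(sp.lambda_c, sp.lambda_n) for sp in pool.species
            )
            bound = self.delta ** 2 / lam_min
            if self.supply_low < 100 * bound:
                raise PoolError(
                    "supply_low violates the high-supply regime: "
                    f"{self.supply_low} < 100 * max(delta^2/lambda) = {100 * bound}"
                )

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.rng_seed)

    @classmethod
    def from_file(cls, path: str | Path) -> "ModelConfig":
        """Load a config from a YAML (or JSON) mapping of field names."""
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise PoolError(f"unknown config fields: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg


def generate_random_pool(
    K: int,
    M: int,
    rng_seed: int | np.random.Generator = 0,
    lambda_range: tuple[float, float] = (10.0, 100.0),
    yield_range: tuple[float, float] = (0.1, 1.0),
) -> SpeciesPool:
    """Draw a full K x M grid of specialist species with random traits.

    One species is created per (carbon, nitrogen) metabolite pair, so
    ``S = K * M``. Competitive abilities are uniform on ``lambda_range``
    and yields uniform on ``yield_range``. Ties within a resource column
    (a measure-zero event) trigger a redraw.
    """
    if K < 1 or M < 1:
        raise PoolError("K and M must be >= 1")
    for lo, hi in (lambda_range, yield_range):
        if not (0 < lo < hi):
            raise PoolError(f"invalid range ({lo}, {hi}): need 0 < low < high")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    for _ in range(100):
        species = []
        sid = 0
        for i in range(1, K + 1):
            for j in range(1, M + 1):
                lc, ln = rng.uniform(*lambda_range, size=2)
                yc, yn = rng.uniform(*yield_range, size=2)
                species.append(SpeciesTraits(sid, i, j, lc, ln, yc, yn))
                sid += 1
        try:
            return SpeciesPool(K, M, tuple(species))
        except PoolError:  # pragma: no cover - measure-zero tie, redraw
            continue
    raise PoolError("could not draw a tie-free pool")  # pragma: no cover


def generate_equal_stoichiometry_pool(
    K: int,
    M: int,
    rng_seed: int = 0,
    lambda_range: tuple[float, float] = (10.0, 100.0),
    yield_range: tuple[float, float] = (0.1, 1.0),
) -> SpeciesPool:
    """Random full-grid pool with identical C:N stoichiometry.

    Every species gets ``yield_n == yield_c`` (stoichiometry 1), the
    regime in which the model provably has a unique uninvadable state for
    every supply vector and no dynamical instability.
    """
    base = generate_random_pool(K, M, rng_seed, lambda_range, yield_range)
    return SpeciesPool(K, M, tuple(
        replace(sp, yield_n=sp.yield_c) for sp in base.species
    ))


def save_pool(pool: SpeciesPool, path: str | Path) -> None:
    """Write a pool as a CSV with one row per species."""
    # default float formatting is shortest-round-trip exact
    pool.to_frame().to_csv(path, index=False)


def load_pool(path: str | Path | io.IOBase, K: int | None = None,
              M: int | None = None) -> SpeciesPool:
    """Load a pool from delimited text.

    Expects columns ``species_id,i,j,lambda_c,lambda_n,yield_c,yield_n``
    (comma or whitespace separated). K and M default to the largest
    resource index present.
    """
    # comma-separated first (exact round-trip float parsing), then
    # whitespace-delimited as a fallback
    df = pd.read_csv(path, float_precision="round_trip")
    if len(df.columns) == 1:
        if hasattr(path, "seek"):
            path.seek(0)
        df = pd.read_csv(path, sep=r"\s+", float_precision="round_trip")
    missing = set(POOL_COLUMNS) - set(df.columns)
    if missing:
        raise PoolError(f"pool file missing columns: {sorted(missing)}")
    species = tuple(
        SpeciesTraits(int(r.species_id), int(r.i), int(r.j),
                      float(r.lambda_c), float(r.lambda_n),
                      float(r.yield_c), float(r.yield_n))
        for r in df.itertuples()
    )
    K = K if K is not None else int(df["i"].max())
    M = M if M is not None else int(df["j"].max())
    return SpeciesPool(K, M, species)


def competitiveness_ranks(pool: SpeciesPool) -> pd.DataFrame:
    """Rank each species on its two resources.

    Rank 1 is the largest lambda among all species consuming a given
    resource; ``average_rank`` is the mean of the carbon and nitrogen
    ranks. Depends only on the ordering of lambdas, not their magnitudes.
    """
    rank_c: dict[int, int] = {}
    rank_n: dict[int, int] = {}
    for i in range(1, pool.K + 1):
        consumers = sorted(
            pool.carbon_consumers(i), key=lambda sp: -sp.lambda_c
        )
        for r, sp in enumerate(consumers, start=1):
            rank_c[sp.species_id] = r
    for j in range(1, pool.M + 1):
        consumers = sorted(
            pool.nitrogen_consumers(j), key=lambda sp: -sp.lambda_n
        )
        for r, sp in enumerate(consumers, start=1):
            rank_n[sp.species_id] = r
    rows = [
        (sp.species_id, rank_c[sp.species_id], rank_n[sp.species_id],
         (rank_c[sp.species_id] + rank_n[sp.species_id]) / 2)
        for sp in pool.species
    ]
    return pd.DataFrame(
        rows, columns=["species_id", "rank_c", "rank_n", "average_rank"]
    ).set_index("species_id")
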