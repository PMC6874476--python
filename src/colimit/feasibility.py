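"""Steady-state solutions, feasibility, and Monte-Carlo supply sampling.

At steady state each nutrient obeys a mass conservation law

    c_i + sum_{alpha using c_i} B_alpha / Y_alpha(c) = phi_i(c) / delta

(and symmetrically for nitrogen). In the high-supply regime the
concentration ``delta/lambda`` of any growth-limiting nutrient is
negligible against the abiotic scale ``phi/delta``, so the unknowns of a
state reduce to the K+M-dimensional vector X of surviving-species
abundances and non-limiting nutrient concentrations, solving the linear
system ``phi/delta = R_p X``. A state is feasible at a supply vector iff
every entry of X is strictly positive.

An optional exact mode keeps the limiting concentrations ``delta/lambda``
on the right-hand side, which makes the solution an exact fixed point of
the chemostat ODEs — used to cross-validate against direct integration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import scipy.linalg
import scipy.sparse

from .species_pool import ModelConfig, SpeciesPool
from .state_enumeration import CommunityState, Resource

__all__ = [
    "SupplyVector",
    "StateSolution",
    "FeasibilityReport",
    "DegenerateStateError",
    "build_resource_matrix",
    "solve_state",
    "sample_supply_vectors",
    "sample_supply_array",
    "monte_carlo_feasibility",
    "classify_structural_stability",
]

POSITIVITY_TOL = 1e-12


class DegenerateStateError(np.linalg.LinAlgError):
    """The state's resource matrix is singular (feasible only on a
    measure-zero subset of supply space)."""


@dataclass(frozen=True)
class SupplyVector:
    """Nutrient supply rates phi and the chemostat dilution rate delta."""

    phi_c: np.ndarray
    phi_n: np.ndarray
    delta: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "phi_c", np.asarray(self.phi_c, float))
        object.__setattr__(self, "phi_n", np.asarray(self.phi_n, float))

    @property
    def phi(self) -> np.ndarray:
        """Concatenated (K+M,) supply vector, carbons first."""
        return np.concatenate([self.phi_c, self.phi_n])

    @property
    def balance_ratio(self) -> float:
        """Total carbon supply over total nitrogen supply."""
        return float(self.phi_c.sum() / self.phi_n.sum())


@dataclass
class StateSolution:
    """Solution X of the conservation system for one state.

    ``columns`` labels each entry: ``("B", species_id)`` for an abundance,
    or a resource key for a non-limiting concentration.
    """

    state: CommunityState
    X: np.ndarray
    columns: list[tuple]
    feasible: bool

    def abundance(self, species_id: int) -> float:
        return float(self.X[self.columns.index(("B", species_id))])

    def concentration(self, resource: Resource) -> float:
        return float(self.X[self.columns.index(resource)])

    @property
    def abundances(self) -> dict[int, float]:
        return {
            col[1]: float(x)
            for col, x in zip(self.columns, self.X)
            if col[0] == "B"
        }


def _resources(pool: SpeciesPool) -> list[Resource]:
    return [("c", i) for i in range(1, pool.K + 1)] + [
        ("n", j) for j in range(1, pool.M + 1)
    ]


def build_resource_matrix(
    pool: SpeciesPool, state: CommunityState
) -> tuple[np.ndarray, list[tuple]]:
    """Assemble the (K+M) x (K+M) matrix R_p of a state.

    Rows are metabolites (carbons then nitrogens); columns are the entries
    of X: one abundance per surviving species (sorted by id), then one
    concentration per non-limiting metabolite. Entries are inverse yields
    ``1/Y`` where a species consumes the row's metabolite, and 1 on a
    non-limiting metabolite's own concentration column.

    Raises `DegenerateStateError` when R_p is singular.
    """
    resources = _resources(pool)
    row_of = {res: r for r, res in enumerate(resources)}
    limited = state.limited_resources
    columns: list[tuple] = [("B", sid) for sid in sorted(state.species_ids)]
    columns += [res for res in resources if res not in limited]
    n = pool.K + pool.M
    if len(columns) != n:  # pragma: no cover - guaranteed by Rule 1
        raise ValueError("state does not define a square conservation system")
    R = np.zeros((n, n))
    for k, col in enumerate(columns):
        if col[0] == "B":
            sp = pool.by_id(col[1])
            R[row_of[("c", sp.carbon_index)], k] = 1.0 / sp.yield_c
            R[row_of[("n", sp.nitrogen_index)], k] = 1.0 / sp.yield_n
        else:
            R[row_of[col], k] = 1.0
    # cheap conditioning check doubling as det(R) == 0 detection
    if np.linalg.matrix_rank(R) < n:
        raise DegenerateStateError(
            f"degenerate state {state!r}: singular resource matrix"
        )
    return R, columns


def _rhs(
    pool: SpeciesPool,
    state: CommunityState,
    supply: SupplyVector,
    exact: bool,
) -> np.ndarray:
    rhs = supply.phi / supply.delta
    if exact:
        resources = _resources(pool)
        row_of = {res: r for r, res in enumerate(resources)}
        for sid, res in state.assignments:
            sp = pool.by_id(sid)
            lam = sp.lambda_c if res[0] == "c" else sp.lambda_n
            rhs[row_of[res]] -= supply.delta / lam
    return rhs


def solve_state(
    pool: SpeciesPool,
    state: CommunityState,
    supply: SupplyVector,
    exact: bool = False,
) -> StateSolution:
    """Solve ``R_p X = phi/delta`` and flag feasibility (all X > 0).

    With ``exact=True`` the limiting-nutrient concentrations
    ``delta/lambda`` are retained on the right-hand side instead of being
    dropped, yielding an exact ODE fixed point.
    """
    R, columns = build_resource_matrix(pool, state)
    X = np.linalg.solve(R, _rhs(pool, state, supply, exact))
    feasible = bool(np.all(X > POSITIVITY_TOL))
    return StateSolution(state=state, X=X, columns=columns, feasible=feasible)


def sample_supply_array(
    config: ModelConfig, K: int, M: int, n_samples: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Uniform i.i.d. supply rates, shape (K+M, n_samples)."""
    config.validate()
    n = config.n_samples if n_samples is None else n_samples
    rng = config.rng() if rng is None else rng
    return rng.uniform(config.supply_low, config.supply_high, size=(K + M, n))


def sample_supply_vectors(
    config: ModelConfig, K: int, M: int, n_samples: int | None = None
) -> Iterator[SupplyVector]:
    """Stream reproducible random supply vectors (see `sample_supply_array`)."""
    phi = sample_supply_array(config, K, M, n_samples)
    for col in phi.T:
        yield SupplyVector(phi_c=col[:K], phi_n=col[K:], delta=config.delta)


@dataclass
class FeasibilityReport:
    """Monte-Carlo feasibility of a list of states over sampled supplies.

    ``feasible`` is a sparse boolean matrix (states x samples);
    ``fractions`` are the per-state normalized feasible ranges (the
    structural-stability measure); ``phi`` holds the sampled supply rates
    so downstream statistics can recover supply-balance ratios.
    """

    states: list[CommunityState]
    feasible: scipy.sparse.csr_matrix
    fractions: np.ndarray
    phi: np.ndarray
    delta: float
    K: int
    M: int
    skipped_degenerate: list[int] = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return self.phi.shape[1]

    def supply_at(self, sample: int) -> SupplyVector:
        col = self.phi[:, sample]
        return SupplyVector(col[: self.K], col[self.K:], self.delta)

    def balance_ratios(self) -> np.ndarray:
        """Per-sample total-carbon : total-nitrogen supply ratio."""
        return self.phi[: self.K].sum(axis=0) / self.phi[self.K:].sum(axis=0)

    def feasible_state_indices(self, sample: int) -> np.ndarray:
        return self.feasible[:, sample].nonzero()[0]

    def counts_per_sample(self, subset: np.ndarray | None = None) -> np.ndarray:
        """Number of feasible states per sample, optionally over a subset."""
        m = self.feasible if subset is None else self.feasible[subset]
        return np.asarray(m.sum(axis=0)).ravel().astype(int)

    def binomial_se(self) -> np.ndarray:
        p = self.fractions
        return np.sqrt(p * (1 - p) / self.n_samples)


def monte_carlo_feasibility(
    pool: SpeciesPool,
    states: Sequence[CommunityState],
    config: ModelConfig,
    phi: np.ndarray | None = None,
) -> FeasibilityReport:
    """Test every state's feasibility at each sampled supply vector.

    One LU factorization per state is reused across all samples. The
    normalized feasible range of a state is the fraction of samples where
    all entries of its X are positive. Degenerate (singular-matrix) states
    are skipped with a warning.
    """
    config.validate(pool)
    if phi is None:
        phi = sample_supply_array(config, pool.K, pool.M)
    n = phi.shape[1]
    indptr = [0]
    indices: list[np.ndarray] = []
    skipped: list[int] = []
    counts = np.zeros(len(states))
    for k, st in enumerate(states):
        try:
            R, _ = build_resource_matrix(pool, st)
        except DegenerateStateError:
            warnings.warn(f"skipping degenerate state {st!r}")
            skipped.append(k)
            indptr.append(indptr[-1])
            continue
        lu, piv = scipy.linalg.lu_factor(R)
        X = scipy.linalg.lu_solve((lu, piv), phi / config.delta)
        ok = np.nonzero(np.all(X > POSITIVITY_TOL, axis=0))[0]
        counts[k] = ok.size
        indices.append(ok)
        indptr.append(indptr[-1] + ok.size)
    data = np.ones(indptr[-1], dtype=bool)
    all_idx = (
        np.concatenate(indices) if indices else np.empty(0, dtype=int)
    )
    feasible = scipy.sparse.csr_matrix(
        (data, all_idx, np.array(indptr)), shape=(len(states), n)
    )
    return FeasibilityReport(
        states=list(states),
        feasible=feasible,
        fractions=counts / n,
        phi=phi,
        delta=config.delta,
        K=pool.K,
        M=pool.M,
        skipped_degenerate=skipped,
    )


def classify_structural_stability(
    report: FeasibilityReport, threshold: float = 0.1
) -> np.ndarray:
    """Flag states whose normalized feasible range exceeds ``threshold``."""
    return report.fractions > threshold
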