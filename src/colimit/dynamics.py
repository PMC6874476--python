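"""Chemostat dynamics of the community under Liebig colimitation.

The growth rate of species alpha is set by its scarcest essential resource,

    g_alpha(c, n) = min(lambda_c * c, lambda_n * n),

and abundances and nutrient concentrations follow

    dB/dt  = B (g - delta)
    dc_i/dt = phi_i(c) - delta c_i - sum_{alpha using c_i} B g / Y(c)

(nitrogen symmetric). The system is stiff near extinction events, so
integration uses an implicit (BDF) solver and clamps abundances below the
extinction threshold to exactly zero between integration legs.

State vector layout throughout: [B_1..B_S, c_1..c_K, n_1..n_M] with
species in pool order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .feasibility import SupplyVector, solve_state
from .species_pool import ModelConfig, SpeciesPool, SpeciesTraits
from .state_enumeration import CommunityState, Resource

__all__ = [
    "EnvironmentState",
    "Trajectory",
    "TransientError",
    "growth_rate",
    "ode_rhs",
    "integrate",
    "classify_endpoint",
    "steady_environment",
]


class TransientError(RuntimeError):
    """A trajectory had not converged when a steady-state label was asked for."""


@dataclass
class EnvironmentState:
    """Full instantaneous state: abundances B, concentrations c and n."""

    B: np.ndarray
    c: np.ndarray
    n: np.ndarray

    def __post_init__(self) -> None:
        self.B = np.asarray(self.B, float)
        self.c = np.asarray(self.c, float)
        self.n = np.asarray(self.n, float)
        if (self.B < 0).any() or (self.c < 0).any() or (self.n < 0).any():
            raise ValueError("negative abundances or concentrations")

    def pack(self) -> np.ndarray:
        return np.concatenate([self.B, self.c, self.n])

    @classmethod
    def unpack(cls, y: np.ndarray, S: int, K: int) -> "EnvironmentState":
        return cls(B=y[:S], c=y[S:S + K], n=y[S + K:])


@dataclass
class Trajectory:
    """Time series of the integrated system."""

    times: np.ndarray
    states: np.ndarray  # (len(times), S+K+M)
    pool: SpeciesPool

    def endpoint(self) -> EnvironmentState:
        return EnvironmentState.unpack(
            self.states[-1], self.pool.S, self.pool.K
        )

    def to_frame(self) -> pd.DataFrame:
        cols = (
            [f"B_{sp.species_id}" for sp in self.pool.species]
            + [f"c_{i}" for i in range(1, self.pool.K + 1)]
            + [f"n_{j}" for j in range(1, self.pool.M + 1)]
        )
        df = pd.DataFrame(self.states, columns=cols)
        df.insert(0, "time", self.times)
        return df


def growth_rate(
    species: SpeciesTraits, c: float, n: float
) -> tuple[float, str]:
    """Liebig growth rate and the limiting resource label.

    Returns ``(min(lambda_c*c, lambda_n*n), which)`` with ``which`` one of
    ``"c"``, ``"n"`` or ``"tie"``. Ties are measure-zero for generic
    parameters and cannot be assigned a limiting resource.
    """
    if c < 0 or n < 0:
        raise ValueError("negative concentration passed to growth_rate")
    gc = species.lambda_c * c
    gn = species.lambda_n * n
    if gc < gn:
        return gc, "c"
    if gn < gc:
        return gn, "n"
    return gc, "tie"


def _arrays(pool: SpeciesPool):
    lc = np.array([sp.lambda_c for sp in pool.species])
    ln = np.array([sp.lambda_n for sp in pool.species])
    yc = np.array([sp.yield_c for sp in pool.species])
    yn = np.array([sp.yield_n for sp in pool.species])
    ci = np.array([sp.carbon_index - 1 for sp in pool.species])
    nj = np.array([sp.nitrogen_index - 1 for sp in pool.species])
    return lc, ln, yc, yn, ci, nj


def _rhs_vec(y, pool, phi, delta, arrays):
    lc, ln, yc, yn, ci, nj = arrays
    S, K, M = pool.S, pool.K, pool.M
    B = y[:S]
    c = y[S:S + K]
    n = y[S + K:]
    g = np.minimum(lc * c[ci], ln * n[nj])
    dB = B * (g - delta)
    uptake = B * g
    dc = phi[:K] - delta * c
    np.subtract.at(dc, ci, uptake / yc)
    dn = phi[K:] - delta * n
    np.subtract.at(dn, nj, uptake / yn)
    return np.concatenate([dB, dc, dn])


def ode_rhs(
    pool: SpeciesPool, supply: SupplyVector, state: EnvironmentState
) -> np.ndarray:
    """Time derivative of [B, c, n] at the given state."""
    if len(supply.phi_c) != pool.K or len(supply.phi_n) != pool.M:
        raise ValueError("supply dimensions do not match pool")
    return _rhs_vec(
        state.pack(), pool, supply.phi, supply.delta, _arrays(pool)
    )


def integrate(
    pool: SpeciesPool,
    supply: SupplyVector,
    initial: EnvironmentState,
    t_end: float,
    config: ModelConfig | None = None,
    n_points: int = 200,
) -> Trajectory:
    """Integrate the chemostat ODEs with a stiff (BDF) solver.

    The time window is split into legs; after each leg any abundance below
    the extinction threshold is clamped to exactly zero (and, having
    dB/dt = 0 at B = 0, stays extinct). Negative round-off in
    concentrations is clamped to zero as well.
    """
    config = config or ModelConfig()
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    arrays = _arrays(pool)
    phi, delta = supply.phi, supply.delta
    S = pool.S
    n_legs = 10
    edges = np.linspace(0.0, t_end, n_legs + 1)
    y = initial.pack().copy()
    times = [0.0]
    states = [y.copy()]
    for a, b in zip(edges[:-1], edges[1:]):
        t_eval = np.linspace(a, b, max(2, n_points // n_legs))[1:]
        sol = solve_ivp(
            lambda t, yy: _rhs_vec(yy, pool, phi, delta, arrays),
            (a, b),
            y,
            method="BDF",
            t_eval=t_eval,
            rtol=config.rtol,
            atol=config.atol,
        )
        if not sol.success:
            raise RuntimeError(
                f"ODE solver failed at t={sol.t[-1] if len(sol.t) else a}: "
                f"{sol.message}"
            )
        times.extend(sol.t)
        states.extend(sol.y.T)
        y = sol.y[:, -1].copy()
        y[:S][y[:S] < config.extinction_threshold] = 0.0
        y[S:] = np.maximum(y[S:], 0.0)
        states[-1] = y.copy()
    return Trajectory(np.array(times), np.vstack(states), pool)


def classify_endpoint(
    trajectory: Trajectory,
    pool: SpeciesPool,
    config: ModelConfig | None = None,
    convergence_tol: float = 1e-6,
) -> CommunityState:
    """Map a converged trajectory to its steady-state label.

    Surviving species are those above the extinction threshold at the
    endpoint; each is labelled with its Liebig-limiting resource.
    Convergence requires the maximum relative change of every variable
    over the last 10% of the window to be below ``convergence_tol``;
    otherwise a `TransientError` is raised (the caller may extend t_end).
    """
    config = config or ModelConfig()
    t, ys = trajectory.times, trajectory.states
    tail = t >= t[-1] - 0.1 * (t[-1] - t[0])
    seg = ys[tail]
    scale = np.maximum(np.abs(seg).max(axis=0), 1e-30)
    rel_change = (seg.max(axis=0) - seg.min(axis=0)) / scale
    # ignore variables that are numerically extinct throughout the tail
    alive = np.abs(seg).max(axis=0) > config.extinction_threshold
    if np.any(rel_change[alive] > convergence_tol):
        raise TransientError(
            f"trajectory not converged: max relative tail change "
            f"{rel_change[alive].max():.3g} > {convergence_tol}"
        )
    end = trajectory.endpoint()
    pairs: list[tuple[int, Resource]] = []
    for k, sp in enumerate(pool.species):
        if end.B[k] <= config.extinction_threshold:
            continue
        _, which = growth_rate(
            sp, end.c[sp.carbon_index - 1], end.n[sp.nitrogen_index - 1]
        )
        if which == "tie":
            raise TransientError(
                f"species {sp.species_id} sits on a Liebig tie; "
                "cannot assign a limiting resource"
            )
        idx = sp.carbon_index if which == "c" else sp.nitrogen_index
        pairs.append((sp.species_id, (which, idx)))
    return CommunityState.from_pairs(pairs)


def steady_environment(
    pool: SpeciesPool, state: CommunityState, supply: SupplyVector
) -> EnvironmentState:
    """Exact ODE fixed point of a feasible state.

    Abundances and non-limiting concentrations come from the exact-mode
    conservation solve; each limited metabolite sits at ``delta/lambda``
    of the species it limits, pinning that species' growth rate to delta.
    """
    sol = solve_state(pool, state, supply, exact=True)
    B = np.zeros(pool.S)
    c = np.zeros(pool.K)
    n = np.zeros(pool.M)
    pos = {sp.species_id: k for k, sp in enumerate(pool.species)}
    for col, x in zip(sol.columns, sol.X):
        if col[0] == "B":
            B[pos[col[1]]] = x
        elif col[0] == "c":
            c[col[1] - 1] = x
        else:
            n[col[1] - 1] = x
    for sid, res in state.assignments:
        sp = pool.by_id(sid)
        if res[0] == "c":
            c[res[1] - 1] = supply.delta / sp.lambda_c
        else:
            n[res[1] - 1] = supply.delta / sp.lambda_n
    return EnvironmentState(B=B, c=c, n=n)
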