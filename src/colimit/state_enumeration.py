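"""Enumeration of community steady states and invadability classification.

A steady state of the chemostat is labelled by the set of surviving species
together with each one's growth-limiting nutrient (its carbon or its
nitrogen source). Competitive exclusion constrains which labels are
realizable:

* Rule 1 — each metabolite limits the growth of at most one species;
* Rule 2 — every species using a metabolite non-limitingly must be
  strictly more competitive for it (larger lambda) than the species the
  metabolite limits.

In the high-supply regime both the set of realizable states and their
invadability depend only on the rank order of competitive abilities, which
makes exhaustive enumeration a pure combinatorial search: choose at most
one carbon-limited species per carbon metabolite, eliminate species
out-competed on carbon, then choose admissible nitrogen-limited additions
per nitrogen metabolite. The number of species in any state is bounded by
K + M, and the raw label space has size 3^S.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .species_pool import SpeciesPool, SpeciesTraits

__all__ = [
    "Resource",
    "CommunityState",
    "candidate_assignments",
    "satisfies_exclusion_rules",
    "enumerate_steady_states",
    "construct_uninvadable",
    "is_uninvadable",
    "enumerate_uninvadable",
]

#: A resource key: ("c", i) for carbon metabolite i, ("n", j) for nitrogen j.
Resource = tuple[str, int]

BRUTE_FORCE_GUARD = 16


@dataclass(frozen=True)
class CommunityState:
    """A steady-state label: frozen set of (species_id, limiting resource).

    The limiting resource of a surviving species is either its carbon
    source ``("c", i)`` or its nitrogen source ``("n", j)``. Abundances are
    deliberately not part of the label.
    """

    assignments: frozenset[tuple[int, Resource]]

    @classmethod
    def from_pairs(
        cls, pairs: Sequence[tuple[int, Resource]]
    ) -> "CommunityState":
        return cls(frozenset(pairs))

    @property
    def species_ids(self) -> frozenset[int]:
        return frozenset(sid for sid, _ in self.assignments)

    @property
    def limited_resources(self) -> frozenset[Resource]:
        return frozenset(res for _, res in self.assignments)

    @property
    def richness(self) -> int:
        return len(self.assignments)

    @property
    def is_empty(self) -> bool:
        return not self.assignments

    def limiting_species(self, resource: Resource) -> int | None:
        for sid, res in self.assignments:
            if res == resource:
                return sid
        return None

    def sorted_pairs(self) -> list[tuple[int, Resource]]:
        return sorted(self.assignments)

    def __repr__(self) -> str:  # compact, stable
        parts = [
            f"{sid}:{kind}{idx}" for sid, (kind, idx) in self.sorted_pairs()
        ]
        return "State{" + ", ".join(parts) + "}"


def candidate_assignments(pool: SpeciesPool) -> Iterator[CommunityState]:
    """Stream all 3^S raw assignments species -> {absent, C-lim, N-lim}.

    This is the brute-force label space; most of these violate the
    exclusion rules. Guarded to S <= 16 — use the structured search
    (`enumerate_steady_states`) beyond that.
    """
    if pool.S > BRUTE_FORCE_GUARD:
        raise ValueError(
            f"S={pool.S} too large for brute-force streaming "
            f"(guard {BRUTE_FORCE_GUARD}); use the structured search"
        )
    for choice in itertools.product(range(3), repeat=pool.S):
        pairs: list[tuple[int, Resource]] = []
        for sp, c in zip(pool.species, choice):
            if c == 1:
                pairs.append((sp.species_id, ("c", sp.carbon_index)))
            elif c == 2:
                pairs.append((sp.species_id, ("n", sp.nitrogen_index)))
        yield CommunityState.from_pairs(pairs)


def satisfies_exclusion_rules(
    pool: SpeciesPool, state: CommunityState
) -> tuple[bool, list[str]]:
    """Check Rules 1-2 for a candidate state; returns (ok, violations)."""
    violations: list[str] = []
    limiter: dict[Resource, SpeciesTraits] = {}
    members: list[SpeciesTraits] = []
    for sid, res in state.sorted_pairs():
        sp = pool.by_id(sid)
        own = {("c", sp.carbon_index), ("n", sp.nitrogen_index)}
        if res not in own:
            violations.append(
                f"species {sid} labelled limited by {res} it does not consume"
            )
            continue
        if res in limiter:
            violations.append(
                f"Rule 1: {res} limits both species "
                f"{limiter[res].species_id} and {sid}"
            )
        else:
            limiter[res] = sp
        members.append(sp)
    for sp in members:
        for kind, idx, lam in (
            ("c", sp.carbon_index, sp.lambda_c),
            ("n", sp.nitrogen_index, sp.lambda_n),
        ):
            res: Resource = (kind, idx)
            lim = limiter.get(res)
            if lim is None or lim.species_id == sp.species_id:
                continue
            lim_lam = lim.lambda_c if kind == "c" else lim.lambda_n
            if lam <= lim_lam:
                violations.append(
                    f"Rule 2: species {sp.species_id} uses {res} "
                    f"non-limitingly but is less competitive than the "
                    f"limited species {lim.species_id}"
                )
    return (not violations, violations)


def _c_selections(pool: SpeciesPool) -> Iterator[dict[int, SpeciesTraits]]:
    """All ways to pick at most one C-limited species per carbon metabolite."""
    per_carbon: list[list[SpeciesTraits | None]] = []
    for i in range(1, pool.K + 1):
        per_carbon.append([None] + pool.carbon_consumers(i))
    for combo in itertools.product(*per_carbon):
        yield {
            i + 1: sp for i, sp in enumerate(combo) if sp is not None
        }


def _eliminate_on_carbon(
    pool: SpeciesPool, c_sel: dict[int, SpeciesTraits]
) -> list[SpeciesTraits]:
    """Species that can still grow on carbon given the C-limited choice.

    A species is eliminated if its carbon is limited by a strictly more
    competitive species. C-limited species themselves are excluded from
    the returned list (they are already placed)."""
    chosen = {sp.species_id for sp in c_sel.values()}
    survivors = []
    for sp in pool.species:
        if sp.species_id in chosen:
            continue
        lim = c_sel.get(sp.carbon_index)
        if lim is not None and sp.lambda_c < lim.lambda_c:
            continue
        survivors.append(sp)
    return survivors


def enumerate_steady_states(pool: SpeciesPool) -> list[CommunityState]:
    """All states satisfying Rules 1-2, via the two-step structured search.

    Step 1 picks the C-limited species (at most one per carbon); Step 2
    eliminates species out-competed on carbon, then per nitrogen metabolite
    adds any one admissible N-limited species or none. Includes the empty
    community. Agrees with brute-force filtering of all 3^S assignments.
    """
    out: set[CommunityState] = set()
    for c_sel in _c_selections(pool):
        base = [
            (sp.species_id, ("c", i)) for i, sp in c_sel.items()
        ]
        candidates = _eliminate_on_carbon(pool, c_sel)
        per_nitrogen: list[list[SpeciesTraits | None]] = []
        for j in range(1, pool.M + 1):
            lim_lns = [
                sp.lambda_n for sp in c_sel.values()
                if sp.nitrogen_index == j
            ]
            cap = min(lim_lns) if lim_lns else math.inf
            admissible: list[SpeciesTraits | None] = [None]
            for sp in candidates:
                if sp.nitrogen_index == j and sp.lambda_n < cap:
                    admissible.append(sp)
            per_nitrogen.append(admissible)
        for combo in itertools.product(*per_nitrogen):
            pairs = list(base)
            for j, sp in enumerate(combo, start=1):
                if sp is not None:
                    pairs.append((sp.species_id, ("n", j)))
            out.add(CommunityState.from_pairs(pairs))
    return sorted(out, key=lambda s: (s.richness, s.sorted_pairs()))


def construct_uninvadable(
    pool: SpeciesPool, c_limited_selection: dict[int, int] | dict[int, SpeciesTraits]
) -> CommunityState | None:
    """Greedy completion of a C-limited selection into an uninvadable state.

    ``c_limited_selection`` maps carbon index -> species (or species_id).
    For each nitrogen metabolite the most competitive carbon-admissible
    consumer is added as N-limited; the construction fails (returns None)
    if for some nitrogen that top candidate out-competes a C-limited
    species using it — such a candidate invades every state built on this
    C-selection.
    """
    c_sel: dict[int, SpeciesTraits] = {}
    for i, v in c_limited_selection.items():
        sp = v if isinstance(v, SpeciesTraits) else pool.by_id(v)
        if sp.carbon_index != i:
            raise ValueError(
                f"species {sp.species_id} does not consume carbon {i}"
            )
        c_sel[i] = sp
    pairs: list[tuple[int, Resource]] = [
        (sp.species_id, ("c", i)) for i, sp in c_sel.items()
    ]
    candidates = _eliminate_on_carbon(pool, c_sel)
    for j in range(1, pool.M + 1):
        users = [sp for sp in candidates if sp.nitrogen_index == j]
        if not users:
            continue
        top = max(users, key=lambda sp: sp.lambda_n)
        lim_lns = [
            sp.lambda_n for sp in c_sel.values() if sp.nitrogen_index == j
        ]
        if lim_lns and top.lambda_n > min(lim_lns):
            return None
        pairs.append((top.species_id, ("n", j)))
    return CommunityState.from_pairs(pairs)


def is_uninvadable(
    pool: SpeciesPool, state: CommunityState
) -> tuple[bool, list[int]]:
    """Invasion test in the high-supply regime (rank order only).

    An absent species invades iff it can grow on both of its resources:
    each resource is either not limiting anyone (macroscopic concentration)
    or limited by a strictly less competitive species. Returns
    (uninvadable, list of successful invader ids).
    """
    limiter: dict[Resource, SpeciesTraits] = {
        res: pool.by_id(sid) for sid, res in state.assignments
    }
    present = state.species_ids
    invaders: list[int] = []
    for sp in pool.species:
        if sp.species_id in present:
            continue
        lim_c = limiter.get(("c", sp.carbon_index))
        ok_c = lim_c is None or sp.lambda_c > lim_c.lambda_c
        lim_n = limiter.get(("n", sp.nitrogen_index))
        ok_n = lim_n is None or sp.lambda_n > lim_n.lambda_n
        if ok_c and ok_n:
            invaders.append(sp.species_id)
    return (not invaders, invaders)


def _enumerate_uninvadable_vectorized(pool: SpeciesPool) -> list[CommunityState]:
    """Exhaustive sweep over all C-limited selections, chunked over numpy.

    Equivalent to calling `construct_uninvadable` for every selection; the
    selections are encoded as a cartesian product of per-carbon choices
    (-1 for "no C-limited species on this carbon").
    """
    S = pool.S
    carbon = np.array([sp.carbon_index - 1 for sp in pool.species])
    nitrogen = np.array([sp.nitrogen_index - 1 for sp in pool.species])
    lc = np.array([sp.lambda_c for sp in pool.species])
    ln = np.array([sp.lambda_n for sp in pool.species])
    sids = np.array([sp.species_id for sp in pool.species])

    choices = [
        [-1] + [k for k in range(S) if carbon[k] == i]
        for i in range(pool.K)
    ]
    total = math.prod(len(c) for c in choices)
    out: set[CommunityState] = set()
    chunk = 20_000
    prod_iter = itertools.product(*choices)
    while True:
        block = list(itertools.islice(prod_iter, chunk))
        if not block:
            break
        sel = np.array(block)                      # (Q, K) species idx or -1
        Q = sel.shape[0]
        # lambda_c of the limiting species per carbon (0 where none)
        lim_lc = np.where(sel >= 0, lc[np.clip(sel, 0, None)], 0.0)  # (Q, K)
        is_clim = sel[:, carbon] == np.arange(S)[None, :]            # (Q, S)
        blocked = (lc[None, :] < lim_lc[:, carbon]) & ~is_clim       # (Q, S)
        candidate = ~blocked & ~is_clim                              # (Q, S)
        # min lambda_n over C-limited species per nitrogen metabolite
        min_clim_ln = np.full((Q, pool.M), np.inf)
        for i in range(pool.K):
            s = sel[:, i]
            has = s >= 0
            if not has.any():
                continue
            rows = np.nonzero(has)[0]
            cols = nitrogen[s[has]]
            np.minimum.at(min_clim_ln, (rows, cols), ln[s[has]])
        # top carbon-admissible candidate per nitrogen metabolite
        cand_ln = np.where(candidate, ln[None, :], -np.inf)          # (Q, S)
        top_val = np.full((Q, pool.M), -np.inf)
        top_idx = np.full((Q, pool.M), -1)
        for j in range(pool.M):
            users = np.nonzero(nitrogen == j)[0]
            if users.size == 0:
                continue
            sub = cand_ln[:, users]                                   # (Q, U)
            arg = np.argmax(sub, axis=1)
            val = sub[np.arange(Q), arg]
            top_val[:, j] = val
            top_idx[:, j] = np.where(np.isfinite(val), users[arg], -1)
        ok = np.all(
            (top_val == -np.inf) | (top_val < min_clim_ln), axis=1
        )
        for q in np.nonzero(ok)[0]:
            pairs: list[tuple[int, Resource]] = []
            for i in range(pool.K):
                s = sel[q, i]
                if s >= 0:
                    pairs.append((int(sids[s]), ("c", i + 1)))
            for j in range(pool.M):
                s = top_idx[q, j]
                if s >= 0:
                    pairs.append((int(sids[s]), ("n", j + 1)))
            out.add(CommunityState.from_pairs(pairs))
    return sorted(out, key=lambda s: (s.richness, s.sorted_pairs()))


def enumerate_uninvadable(pool: SpeciesPool) -> list[CommunityState]:
    """All uninvadable steady states of the pool.

    Runs the greedy construction over every C-limited selection (at most
    one uninvadable state exists per selection); duplicates across
    selections are removed. Equal to filtering `enumerate_steady_states`
    through `is_uninvadable`.
    """
    return _enumerate_uninvadable_vectorized(pool)


def states_to_frame(states: Sequence[CommunityState]) -> pd.DataFrame:
    """Tidy table with one row per (state_id, species_id, limiting_resource)."""
    rows = []
    for k, st in enumerate(states):
        if st.is_empty:
            rows.append((k, -1, ""))
        for sid, (kind, idx) in st.sorted_pairs():
            rows.append((k, sid, f"{kind}{idx}"))
    return pd.DataFrame(rows, columns=["state_id", "species_id", "limiting_resource"])
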