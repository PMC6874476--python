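"""Enumeration of steady states, exclusion rules and invadability.

The brute-force oracles here are written independently of the package's
structured search: they re-derive Rule 1/Rule 2 and the invasion test by
direct iteration over species and resources.
"""

import itertools
import math

import numpy as np
import pytest

from colimit import (
    CommunityState,
    SpeciesPool,
    SpeciesTraits,
    candidate_assignments,
    construct_uninvadable,
    enumerate_steady_states,
    enumerate_uninvadable,
    generate_random_pool,
    is_uninvadable,
    satisfies_exclusion_rules,
)


def brute_force_states(pool: SpeciesPool) -> set[CommunityState]:
    """Oracle: filter all 3^S labels through a from-scratch rule check."""
    lam = {}
    res_of = {}
    for sp in pool.species:
        lam[sp.species_id, "c"] = sp.lambda_c
        lam[sp.species_id, "n"] = sp.lambda_n
        res_of[sp.species_id] = {
            "c": ("c", sp.carbon_index), "n": ("n", sp.nitrogen_index)
        }
    ok_states = set()
    for choice in itertools.product(["absent", "c", "n"], repeat=pool.S):
        pairs = [
            (sp.species_id, res_of[sp.species_id][lim])
            for sp, lim in zip(pool.species, choice)
            if lim != "absent"
        ]
        # Rule 1: no metabolite limits two species
        limited = [r for _, r in pairs]
        if len(set(limited)) != len(limited):
            continue
        limiter = {r: sid for sid, r in pairs}
        # Rule 2: non-limited users must out-compete the limited species
        good = True
        for sp, lim in zip(pool.species, choice):
            if lim == "absent":
                continue
            for side in ("c", "n"):
                r = res_of[sp.species_id][side]
                other = limiter.get(r)
                if other is not None and other != sp.species_id:
                    if lam[sp.species_id, side] < lam[other, side]:
                        good = False
        if good:
            ok_states.add(CommunityState.from_pairs(pairs))
    return ok_states


def brute_force_uninvadable(pool, states) -> set[CommunityState]:
    """Oracle: a state is uninvadable iff no absent species can grow on
    both its resources given the limiting species' ranks."""
    out = set()
    for st in states:
        limiter = {r: sid for sid, r in st.assignments}
        invaded = False
        for sp in pool.species:
            if sp.species_id in st.species_ids:
                continue
            blocks = 0
            for side, lam, idx in (
                ("c", sp.lambda_c, sp.carbon_index),
                ("n", sp.lambda_n, sp.nitrogen_index),
            ):
                holder = limiter.get((side, idx))
                if holder is not None:
                    other = pool.by_id(holder)
                    held = other.lambda_c if side == "c" else other.lambda_n
                    if lam < held:
                        blocks += 1
            if blocks == 0:
                invaded = True
                break
        if not invaded:
            out.add(st)
    return out


class TestCandidateAssignments:
    @pytest.mark.parametrize("K,M,expected", [(2, 2, 81), (1, 1, 3), (2, 1, 9)])
    def test_count_is_three_to_the_S(self, K, M, expected):
        pool = generate_random_pool(K, M, 0)
        labels = list(candidate_assignments(pool))
        assert len(labels) == expected == 3 ** pool.S
        assert len(set(labels)) == expected

    def test_guard_on_large_pools(self):
        pool = generate_random_pool(5, 5, 0)
        with pytest.raises(ValueError, match="structured search"):
            next(candidate_assignments(pool))


class TestExclusionRules:
    def test_two_species_limited_by_same_metabolite(self):
        pool = generate_random_pool(1, 2, 0)  # both species share c1
        s0, s1 = pool.species
        st = CommunityState.from_pairs(
            [(s0.species_id, ("c", 1)), (s1.species_id, ("c", 1))]
        )
        ok, report = satisfies_exclusion_rules(pool, st)
        assert not ok and any("Rule 1" in v for v in report)

    def test_nonlimited_user_must_outcompete(self):
        weak = SpeciesTraits(0, 1, 1, 30.0, 20.0, 0.5, 0.5)
        strong = SpeciesTraits(1, 1, 2, 60.0, 25.0, 0.5, 0.5)
        pool = SpeciesPool(1, 2, (weak, strong))
        good = CommunityState.from_pairs([(0, ("c", 1)), (1, ("n", 2))])
        assert satisfies_exclusion_rules(pool, good)[0]
        # swapping roles puts the weaker species as the non-limited user
        bad = CommunityState.from_pairs([(1, ("c", 1)), (0, ("n", 1))])
        ok, report = satisfies_exclusion_rules(pool, bad)
        assert not ok and any("Rule 2" in v for v in report)

    def test_empty_state_vacuously_valid(self, pool_2x2):
        assert satisfies_exclusion_rules(
            pool_2x2, CommunityState.from_pairs([])
        )[0]


class TestEnumeration:
    def test_single_species_pool_has_three_states(self, pool_1x1):
        states = enumerate_steady_states(pool_1x1)
        assert set(states) == {
            CommunityState.from_pairs([]),
            CommunityState.from_pairs([(0, ("c", 1))]),
            CommunityState.from_pairs([(0, ("n", 1))]),
        }

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force(self, seed):
        pool = generate_random_pool(2, 2, seed)
        assert set(enumerate_steady_states(pool)) == brute_force_states(pool)

    def test_soundness_and_bound(self, pool_2x2):
        states = enumerate_steady_states(pool_2x2)
        assert len(states) <= 3 ** pool_2x2.S
        for st in states:
            assert satisfies_exclusion_rules(pool_2x2, st)[0]
            assert st.richness <= pool_2x2.K + pool_2x2.M


class TestUninvadable:
    def test_single_species_states_uninvadable(self, pool_1x1):
        uninv = set(enumerate_uninvadable(pool_1x1))
        assert uninv == {
            CommunityState.from_pairs([(0, ("c", 1))]),
            CommunityState.from_pairs([(0, ("n", 1))]),
        }
        # the empty state is invadable by the lone species
        ok, invaders = is_uninvadable(pool_1x1, CommunityState.from_pairs([]))
        assert not ok and invaders == [0]

    def test_greedy_construction_single_nitrogen(self):
        a = SpeciesTraits(0, 1, 1, 30.0, 20.0, 0.5, 0.5)
        b = SpeciesTraits(1, 1, 1, 40.0, 50.0, 0.5, 0.5)
        pool = SpeciesPool(1, 1, (a, b))
        st = construct_uninvadable(pool, {})
        # empty C-selection: the larger-lambda_n species is added N-limited
        assert st == CommunityState.from_pairs([(1, ("n", 1))])
        assert is_uninvadable(pool, st)[0]

    def test_construction_blocked_by_rule2(self):
        # C-limited species has the smaller lambda_n on the shared nitrogen,
        # so the top nitrogen candidate would violate Rule 2
        clim = SpeciesTraits(0, 1, 1, 30.0, 20.0, 0.5, 0.5)
        inv = SpeciesTraits(1, 2, 1, 40.0, 50.0, 0.5, 0.5)
        pool = SpeciesPool(2, 1, (clim, inv))
        assert construct_uninvadable(pool, {1: 0}) is None
        # ... and that candidate indeed invades the bare C-selection state
        ok, invaders = is_uninvadable(
            pool, CommunityState.from_pairs([(0, ("c", 1))])
        )
        assert not ok and 1 in invaders

    def test_top_competitor_selection_is_uninvadable(self):
        pool = generate_random_pool(3, 3, 2)
        top = {}
        for i in range(1, 4):
            top[i] = max(pool.carbon_consumers(i), key=lambda s: s.lambda_c)
        st = construct_uninvadable(pool, {i: sp for i, sp in top.items()})
        assert st is not None and is_uninvadable(pool, st)[0]

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_invasion_oracle(self, seed):
        pool = generate_random_pool(2, 2, seed + 50)
        states = enumerate_steady_states(pool)
        assert set(enumerate_uninvadable(pool)) == brute_force_uninvadable(
            pool, states
        )

    def test_subset_of_all_states(self, pool_2x2):
        all_states = set(enumerate_steady_states(pool_2x2))
        assert set(enumerate_uninvadable(pool_2x2)) <= all_states


class TestRankOrderInvariance:
    def test_enumeration_depends_only_on_lambda_ranks(self):
        pool = generate_random_pool(2, 3, 9)
        # strictly monotone per-column rescaling of all lambdas
        rescaled = SpeciesPool(pool.K, pool.M, tuple(
            SpeciesTraits(sp.species_id, sp.carbon_index, sp.nitrogen_index,
                          2 * sp.lambda_c + 1, sp.lambda_n ** 2,
                          sp.yield_c, sp.yield_n)
            for sp in pool.species
        ))
        assert set(enumerate_steady_states(pool)) == set(
            enumerate_steady_states(rescaled)
        )
        assert set(enumerate_uninvadable(pool)) == set(
            enumerate_uninvadable(rescaled)
        )
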