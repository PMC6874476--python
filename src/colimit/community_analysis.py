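"""Downstream statistics of multistability, diversity and stoichiometry.

Builds on the Monte-Carlo feasibility report and stability labels:

* the distribution of V, the number of simultaneously feasible
  uninvadable dynamically stable states per sampled environment, with a
  Poisson fit to V-1;
* how multistability and species richness depend on the carbon:nitrogen
  supply balance;
* species prevalence versus competitiveness rank, state counts and
  feasible ranges versus richness;
* a sweep over yield (stoichiometry) variation quantifying how much
  stoichiometric diversity is needed for multistability;
* a PCA view of the alternative states' relative abundance profiles in a
  fluctuating environment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .feasibility import (
    FeasibilityReport,
    SupplyVector,
    monte_carlo_feasibility,
    sample_supply_array,
    solve_state,
)
from .species_pool import ModelConfig, SpeciesPool, competitiveness_ranks
from .stability import infer_stability_from_multiplicity
from .state_enumeration import CommunityState, enumerate_uninvadable

__all__ = [
    "MultistabilityStats",
    "multistability_histogram",
    "multistability_vs_balance",
    "richness_and_range_stats",
    "yield_variation_sweep",
    "bin_yield_sweep",
    "pca_state_projection",
    "DEFAULT_YIELD_INTERVALS",
]

DEFAULT_YIELD_INTERVALS = (
    (0.45, 0.55),
    (0.3, 0.7),
    (0.1, 0.9),
    (0.01, 1.0),
)


@dataclass
class MultistabilityStats:
    """Per-sample multistability counts V and the Poisson fit to V-1."""

    V: np.ndarray
    balance_ratio: np.ndarray
    histogram: dict[int, int]
    poisson_rate: float

    @property
    def n_samples(self) -> int:
        return len(self.V)

    @property
    def multistable_fraction(self) -> float:
        return float(np.mean(self.V >= 2))


def multistability_histogram(
    report: FeasibilityReport, stable_mask: np.ndarray
) -> MultistabilityStats:
    """Count feasible stable states per sample and fit Poisson(V-1).

    The maximum-likelihood Poisson rate for V-1 is simply its mean.
    """
    stable_idx = np.nonzero(np.asarray(stable_mask, bool))[0]
    V = report.counts_per_sample(stable_idx)
    vals, counts = np.unique(V, return_counts=True)
    rate = float(np.mean(np.maximum(V, 1) - 1))
    return MultistabilityStats(
        V=V,
        balance_ratio=report.balance_ratios(),
        histogram=dict(zip(vals.tolist(), counts.tolist())),
        poisson_rate=rate,
    )


def _log_ratio_bins(ratios: np.ndarray, n_bins: int) -> tuple[np.ndarray, np.ndarray]:
    logr = np.log10(ratios)
    edges = np.linspace(logr.min(), np.nextafter(logr.max(), np.inf), n_bins + 1)
    idx = np.digitize(logr, edges) - 1
    centers = 10 ** ((edges[:-1] + edges[1:]) / 2)
    return idx, centers


def multistability_vs_balance(
    stats: MultistabilityStats, n_bins: int = 25
) -> pd.DataFrame:
    """Fraction of multistable samples (V >= 2) per supply-ratio bin.

    The ratio axis is total carbon over total nitrogen supply, binned in
    log space; empty bins carry NaN.
    """
    idx, centers = _log_ratio_bins(stats.balance_ratio, n_bins)
    frac = np.full(n_bins, np.nan)
    count = np.zeros(n_bins, dtype=int)
    multi = stats.V >= 2
    for b in range(n_bins):
        sel = idx == b
        count[b] = sel.sum()
        if count[b]:
            frac[b] = multi[sel].mean()
    return pd.DataFrame(
        {"ratio": centers, "multistable_fraction": frac, "n_samples": count}
    )


def richness_and_range_stats(
    report: FeasibilityReport,
    states: list[CommunityState],
    stable_mask: np.ndarray,
    unstable_mask: np.ndarray,
    pool: SpeciesPool,
    n_bins: int = 25,
) -> dict[str, pd.DataFrame]:
    """Diversity and structural-stability summaries.

    Returns four tidy tables:

    ``richness_vs_ratio`` — mean (and SD) richness of feasible stable
    states per log supply-ratio bin;
    ``prevalence`` — per species, the fraction of sampled environments
    where it is present in at least one feasible uninvadable state
    (``prevalence_any``) and in every feasible uninvadable state
    (``prevalence_all``), joined with competitiveness ranks;
    ``counts_vs_richness`` — number of stable / unstable states per
    richness;
    ``range_vs_richness`` — feasible-range distribution of stable states
    grouped by richness.
    """
    stable_mask = np.asarray(stable_mask, bool)
    unstable_mask = np.asarray(unstable_mask, bool)
    richness = np.array([st.richness for st in states])
    F = report.feasible.tocsc()
    n = report.n_samples

    # mean richness of feasible stable states, per sample
    stable_idx = np.nonzero(stable_mask)[0]
    Fs = F[stable_idx]
    sums = np.asarray(
        Fs.multiply(richness[stable_idx][:, None]).sum(axis=0)
    ).ravel()
    counts = np.asarray(Fs.sum(axis=0)).ravel()
    with np.errstate(invalid="ignore"):
        mean_rich = sums / counts
    idx, centers = _log_ratio_bins(report.balance_ratios(), n_bins)
    rows = []
    for b in range(n_bins):
        sel = (idx == b) & (counts > 0)
        if sel.any():
            rows.append(
                (centers[b], mean_rich[sel].mean(), mean_rich[sel].std(),
                 int(sel.sum()))
            )
        else:
            rows.append((centers[b], np.nan, np.nan, 0))
    richness_vs_ratio = pd.DataFrame(
        rows, columns=["ratio", "mean_richness", "sd_richness", "n_samples"]
    )

    # prevalence per species across feasible uninvadable states
    membership = np.zeros((len(states), pool.S), dtype=bool)
    pos = {sp.species_id: k for k, sp in enumerate(pool.species)}
    for s, st in enumerate(states):
        for sid in st.species_ids:
            membership[s, pos[sid]] = True
    Fr = report.feasible.tocsr()
    present_count = Fr.T @ membership.astype(np.int64)  # (samples, S)
    present_any = present_count > 0
    V_all = np.asarray(Fr.sum(axis=0)).ravel()
    present_all = (present_count == V_all[:, None]) & (V_all > 0)[:, None]
    ranks = competitiveness_ranks(pool)
    prevalence = ranks.copy()
    order = [pos[sid] for sid in ranks.index]
    prevalence["prevalence_any"] = present_any.mean(axis=0)[order]
    prevalence["prevalence_all"] = present_all.mean(axis=0)[order]

    rows = []
    for r in np.unique(richness):
        sel = richness == r
        rows.append(
            (int(r), int((sel & stable_mask).sum()),
             int((sel & unstable_mask).sum()))
        )
    counts_vs_richness = pd.DataFrame(
        rows, columns=["richness", "n_stable", "n_unstable"]
    )

    rows = []
    for r in np.unique(richness[stable_mask]):
        fr = report.fractions[stable_mask & (richness == r)]
        rows.append(
            (int(r), len(fr), fr.mean(), np.median(fr), fr.min(), fr.max())
        )
    range_vs_richness = pd.DataFrame(
        rows,
        columns=["richness", "n_states", "mean_fraction", "median_fraction",
                 "min_fraction", "max_fraction"],
    )
    return {
        "richness_vs_ratio": richness_vs_ratio,
        "prevalence": prevalence.reset_index(),
        "counts_vs_richness": counts_vs_richness,
        "range_vs_richness": range_vs_richness,
    }


def yield_variation_sweep(
    base_pool: SpeciesPool,
    yield_intervals: tuple[tuple[float, float], ...] = DEFAULT_YIELD_INTERVALS,
    n_variants_per_interval: int = 1000,
    n_samples: int = 100_000,
    seed: int = 0,
    config: ModelConfig | None = None,
) -> pd.DataFrame:
    """Multistability versus stoichiometric diversity.

    Keeps the base pool's competitive abilities (hence its uninvadable
    state set, which depends only on lambda rank order) and redraws all
    yields from each interval, ``n_variants_per_interval`` times per
    interval. For every variant the fraction of supply samples with two
    or more feasible uninvadable dynamically stable states is recorded
    next to the standard deviation of the species' log stoichiometries
    log(Y(n)/Y(c)).
    """
    config = config or ModelConfig()
    rng = np.random.default_rng(seed)
    uninv = enumerate_uninvadable(base_pool)
    rows = []
    for lo, hi in yield_intervals:
        for _ in range(n_variants_per_interval):
            yields = {
                sp.species_id: (rng.uniform(lo, hi), rng.uniform(lo, hi))
                for sp in base_pool.species
            }
            variant = base_pool.with_yields(yields)
            log_stoich = np.log(
                [sp.yield_n / sp.yield_c for sp in variant.species]
            )
            phi = sample_supply_array(
                config, variant.K, variant.M, n_samples, rng=rng
            )
            report = monte_carlo_feasibility(variant, uninv, config, phi=phi)
            inference = infer_stability_from_multiplicity(report)
            V = report.counts_per_sample(np.nonzero(inference.stable_mask)[0])
            rows.append(
                (lo, hi, float(np.std(log_stoich)), float(np.mean(V >= 2)))
            )
    return pd.DataFrame(
        rows,
        columns=["interval_low", "interval_high", "stoichiometry_log_sd",
                 "multistable_fraction"],
    )


def bin_yield_sweep(sweep: pd.DataFrame, n_bins: int = 50) -> pd.DataFrame:
    """Column-normalized 2-D log-binned histogram of the yield sweep.

    Variants with zero multistability are gathered in a dedicated bottom
    row (log of zero is undefined), matching how the sweep is usually
    displayed.
    """
    x = sweep["stoichiometry_log_sd"].to_numpy()
    y = sweep["multistable_fraction"].to_numpy()
    xpos = x[x > 0]
    xe = np.logspace(
        np.log10(xpos.min()), np.log10(np.nextafter(x.max(), np.inf)), n_bins + 1
    )
    ypos = y[y > 0]
    if ypos.size == 0:
        ye = np.logspace(-6, 0, n_bins + 1)
    else:
        ye = np.logspace(
            np.log10(ypos.min()),
            np.log10(np.nextafter(max(y.max(), ypos.min() * 10), np.inf)),
            n_bins + 1,
        )
    xi = np.clip(np.digitize(x, xe) - 1, 0, n_bins - 1)
    yi = np.where(y > 0, np.clip(np.digitize(y, ye) - 1, 0, n_bins - 1), -1)
    counts = np.zeros((n_bins + 1, n_bins))  # row 0 = "no multistability"
    for a, b in zip(xi, yi):
        counts[b + 1, a] += 1
    colsum = counts.sum(axis=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        norm = 100 * counts / colsum
    rows = ["zero"] + [f"{lo:.3g}-{hi:.3g}" for lo, hi in zip(ye[:-1], ye[1:])]
    cols = [f"{lo:.3g}-{hi:.3g}" for lo, hi in zip(xe[:-1], xe[1:])]
    return pd.DataFrame(norm, index=rows, columns=cols)


def pca_state_projection(
    pool: SpeciesPool,
    center_supply: SupplyVector,
    states: list[CommunityState],
    stable_mask: np.ndarray,
    jitter_fraction: float = 0.1,
    n_samples: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Relative-abundance PCA of the states feasible near one environment.

    Supply rates are jittered uniformly within ``+-jitter_fraction`` of
    the centre; every uninvadable state feasible at a jittered supply
    contributes its relative (sum-to-one) abundance profile, tagged with
    its dynamic-stability label. The first two principal components of the
    pooled profiles are returned per (sample, state).
    """
    if n_samples < 3:
        raise ValueError("need at least 3 samples for a PCA")
    rng = np.random.default_rng(seed)
    stable_mask = np.asarray(stable_mask, bool)
    phi0 = center_supply.phi
    pos = {sp.species_id: k for k, sp in enumerate(pool.species)}
    rows = []
    profiles = []
    for s in range(n_samples):
        phi = phi0 * rng.uniform(
            1 - jitter_fraction, 1 + jitter_fraction, size=phi0.shape
        )
        supply = SupplyVector(
            phi[: pool.K], phi[pool.K:], center_supply.delta
        )
        for k, st in enumerate(states):
            if st.is_empty:
                continue
            sol = solve_state(pool, st, supply)
            if not sol.feasible:
                continue
            prof = np.zeros(pool.S)
            for sid, b in sol.abundances.items():
                prof[pos[sid]] = b
            prof /= prof.sum()
            profiles.append(prof)
            rows.append((s, k, bool(stable_mask[k])))
    if len(profiles) < 3:
        raise ValueError("fewer than 3 feasible profiles near this centre")
    Z = PCA(n_components=2).fit_transform(np.vstack(profiles))
    df = pd.DataFrame(rows, columns=["sample", "state_id", "stable"])
    df["pc1"] = Z[:, 0]
    df["pc2"] = Z[:, 1]
    return df
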