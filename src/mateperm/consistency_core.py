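"""The consistency index Δ̄ and its permutation test.

Δ̄ measures within-respondent similarity of partners on one trait: for each
respondent take the mean absolute difference over all unordered pairs of her
partners' trait values, then average these per-respondent means with equal
weight across respondents. Lower Δ̄ = more consistent mate choice.

The null model reassigns partners to respondents uniformly at random while
preserving each respondent's partner count; the one-tailed p-value is the
fraction of null Δ̄ draws strictly below the observed value (small p =
partners of the same respondent are more alike than random sets of the same
sizes).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .trait_model_io import CohortTable, TraitSlots


@dataclass
class NullDistribution:
    """Permutation samples of Δ̄ under random partner-to-respondent pairing."""

    samples: np.ndarray
    n_perm: int
    seed: int

    @property
    def mean(self) -> float:
        return float(np.mean(self.samples))

    @property
    def sd(self) -> float:
        return float(np.std(self.samples, ddof=1)) if len(self.samples) > 1 else 0.0


@dataclass
class ConsistencyRow:
    trait: str
    observed_delta: float
    expected_delta: float
    expected_sd: float
    p: float
    p_adj: float | None
    n_respondents_informative: int
    n_partners_informative: int


def respondent_mean_pairwise_diff(values: Sequence[float]) -> float:
    """Mean absolute difference over all unordered pairs of one respondent's partners.

    E.g. partners scoring (5, 10, 7, 14) give (5+2+9+3+4+7)/6 = 5.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or len(v) < 2:
        raise ValueError("need at least 2 trait values for one respondent")
    if np.isnan(v).any():
        raise ValueError("missing values must be dropped before calling")
    ja, jb = np.triu_indices(len(v), k=1)
    return float(np.mean(np.abs(v[ja] - v[jb])))


def delta_from_slots(values: np.ndarray, slots: TraitSlots) -> float:
    """Δ̄ for an arbitrary assignment of ``values`` to the slot structure."""
    diffs = np.abs(values[slots.pair_a] - values[slots.pair_b])
    per_group = np.bincount(slots.pair_group, weights=diffs, minlength=slots.n_groups)
    return float(np.mean(per_group / slots.pairs_per_group))


def per_respondent_diffs(values: np.ndarray, slots: TraitSlots) -> np.ndarray:
    """Vector of per-respondent mean pairwise differences for one assignment."""
    diffs = np.abs(values[slots.pair_a] - values[slots.pair_b])
    per_group = np.bincount(slots.pair_group, weights=diffs, minlength=slots.n_groups)
    return per_group / slots.pairs_per_group


def population_delta(cohort: CohortTable, trait: str) -> float:
    """Observed Δ̄ for a trait: equal-weight average of per-respondent means.

    Only informative respondents (>= 2 non-missing partner values) enter.
    """
    slots = cohort.trait_slots(trait)
    if slots.n_groups < 1:
        raise ValueError(f"no informative respondent for trait {trait!r}")
    return delta_from_slots(slots.values, slots)


def _null_samples(slots: TraitSlots, n_perm: int, rng: np.random.Generator,
                  chunk: int = 2000) -> np.ndarray:
    """Vectorised permutation draws of Δ̄: shuffle values across all slots."""
    n = slots.n_slots
    out = np.empty(n_perm)
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        # m independent permutations via argsort of uniform keys
        order = np.argsort(rng.random((m, n)), axis=1)
        V = slots.values[order]                      # (m, n)
        diffs = np.abs(V[:, slots.pair_a] - V[:, slots.pair_b])
        # per-group sums via reduceat (pairs are stored grouped by respondent)
        pair_offsets = np.concatenate([[0], np.cumsum(slots.pairs_per_group)[:-1]])
        sums = np.add.reduceat(diffs, pair_offsets, axis=1)
        out[done:done + m] = (sums / slots.pairs_per_group).mean(axis=1)
        done += m
    return out


def permutation_null(cohort: CohortTable, trait: str, n_perm: int = 10_000,
                     seed: int = 0) -> NullDistribution:
    """Null distribution of Δ̄ under random pairing, partner counts preserved.

    Each draw permutes the informative partners' trait values across all
    informative partner slots (equivalent to reassigning partners while
    keeping every respondent's partner count) and recomputes Δ̄.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    slots = cohort.trait_slots(trait)
    if slots.n_groups < 2:
        raise ValueError(f"need >= 2 informative respondents for trait {trait!r}")
    rng = np.random.default_rng(seed)
    samples = _null_samples(slots, n_perm, rng)
    return NullDistribution(samples=samples, n_perm=n_perm, seed=seed)


def consistency_test(observed: float, null: NullDistribution) -> float:
    """One-tailed permutation p: fraction of null Δ̄ strictly below observed.

    A degenerate zero-variance null (e.g. a constant trait) carries no
    evidence of consistency and returns p = 1.
    """
    if len(null.samples) == 0:
        raise ValueError("empty null distribution")
    if null.sd == 0.0:
        return 1.0
    return float(np.mean(null.samples < observed))


def consistency_table(cohort: CohortTable, traits: Sequence[str] | None = None,
                      n_perm: int = 10_000, seed: int = 0) -> list[ConsistencyRow]:
    """Observed vs expected Δ̄ with permutation p for each trait (no BH yet)."""
    from .association_measures import bh_adjust  # local import to avoid cycle

    traits = list(traits) if traits is not None else cohort.registry.names
    rng = np.random.default_rng(seed)
    rows = []
    for trait in traits:
        slots = cohort.trait_slots(trait)
        obs = delta_from_slots(slots.values, slots)
        null = permutation_null(cohort, trait, n_perm=n_perm,
                                seed=int(rng.integers(2**31 - 1)))
        rows.append(ConsistencyRow(
            trait=trait,
            observed_delta=obs,
            expected_delta=null.mean,
            expected_sd=null.sd,
            p=consistency_test(obs, null),
            p_adj=None,
            n_respondents_informative=slots.n_groups,
            n_partners_informative=slots.n_slots,
        ))
    adj = bh_adjust([r.p for r in rows])
    for r, a in zip(rows, adj):
        r.p_adj = float(a)
    return rows
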