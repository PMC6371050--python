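"""Stepwise-randomization effect size: proportion of partners to relocate.

The effect size of mate-choice consistency on a trait is expressed as the
percentage of partners that must switch respondents before the consistency
index Δ̄ first rises to its random-pairing expectation. One relocation step
is a swap of two partners belonging to different respondents — the only
single move that preserves every respondent's partner count — and counts as
two relocated partners. Candidate swaps are drawn uniformly at random but
only swaps that raise Δ̄ are kept, so the index is gradually elevated and
the count reflects productive relocations. The measure runs from 0%
(observed Δ̄ already at or above the expectation) to a nominal 50%: the
Δ̄-maximal configuration sits about half of all partners away from any
fully consistent one, past which further relocation re-approaches the
initial configuration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .consistency_core import NullDistribution, delta_from_slots
from .trait_model_io import CohortTable, TraitSlots


@dataclass
class EffectSizeEstimate:
    trait: str
    effect_pct: float
    ci_lo: float
    ci_hi: float
    n_runs: int
    seed: int


class RelocationEngine:
    """Random cross-respondent partner swaps with incremental Δ̄ tracking.

    Holds one or several traits' values on a common slot structure; a swap
    moves whole partners, so all tracked traits update together (this is what
    makes residual effect sizes after eliminating another trait's consistency
    meaningful).
    """

    def __init__(self, slots: TraitSlots, rng: np.random.Generator):
        v = slots.values
        self.values = v[:, None].copy() if v.ndim == 1 else v.copy()
        self.slots = slots
        self.rng = rng
        self.n_slots = slots.n_slots
        self.n_traits = self.values.shape[1]
        self.group_of_slot = np.repeat(
            np.arange(slots.n_groups), slots.group_sizes
        )
        # per-group mean pairwise difference, per trait: (n_groups, n_traits)
        self._d = np.empty((slots.n_groups, self.n_traits))
        for g in range(slots.n_groups):
            self._recompute_group(g)
        self._deltas = self._d.mean(axis=0)

    def _recompute_group(self, g: int) -> None:
        off = self.slots.group_offsets[g]
        p = self.slots.group_sizes[g]
        block = self.values[off:off + p]                  # (p, k)
        ja, jb = np.triu_indices(p, k=1)
        self._d[g] = np.abs(block[ja] - block[jb]).mean(axis=0)

    def delta(self, trait_idx: int = 0) -> float:
        return float(self._deltas[trait_idx])

    def swap_random(self) -> None:
        """Swap two uniformly chosen partners of different respondents."""
        rng = self.rng
        a = int(rng.integers(self.n_slots))
        b = int(rng.integers(self.n_slots))
        while self.group_of_slot[a] == self.group_of_slot[b]:
            b = int(rng.integers(self.n_slots))
        self.values[[a, b]] = self.values[[b, a]]
        ga, gb = self.group_of_slot[a], self.group_of_slot[b]
        self._recompute_group(ga)
        self._recompute_group(gb)
        self._deltas = self._d.mean(axis=0)

    def run_until(self, trait_idx: int, target: float,
                  max_proposals: int | None = None) -> int:
        """Gradually elevate Δ̄(trait) to ``target``; return accepted swap count.

        Swaps are proposed uniformly at random between partners of different
        respondents; a proposal is kept only if it strictly raises the focal
        trait's Δ̄ and reverted otherwise, so the index climbs monotonically
        and only kept swaps relocate (and count) partners. Rejected
        proposals leave the configuration untouched.
        """
        if max_proposals is None:
            max_proposals = max(200_000, 500 * self.n_slots)
        rng = self.rng
        accepted = 0
        proposals = 0
        while self.delta(trait_idx) < target:
            if proposals >= max_proposals:
                raise RuntimeError(
                    f"target Δ̄ {target} not reached after {max_proposals} proposals"
                )
            proposals += 1
            a = int(rng.integers(self.n_slots))
            b = int(rng.integers(self.n_slots))
            if self.group_of_slot[a] == self.group_of_slot[b]:
                continue
            ga, gb = self.group_of_slot[a], self.group_of_slot[b]
            old_delta = self._deltas[trait_idx]
            old_d = self._d[[ga, gb]].copy()
            self.values[[a, b]] = self.values[[b, a]]
            self._recompute_group(ga)
            self._recompute_group(gb)
            self._deltas = self._d.mean(axis=0)
            if self._deltas[trait_idx] > old_delta:
                accepted += 1
            else:
                self.values[[a, b]] = self.values[[b, a]]
                self._d[[ga, gb]] = old_d
                self._deltas = self._d.mean(axis=0)
        return accepted


def relocated_pct(n_swaps: int, n_slots: int) -> float:
    """Each swap relocates two partners; express as % of all informative partners."""
    return 100.0 * 2.0 * n_swaps / n_slots


def stepwise_run(cohort: CohortTable, trait: str, target_delta: float,
                 seed: int = 0) -> float:
    """One stepwise randomization run; returns the % of partners relocated."""
    slots = cohort.trait_slots(trait)
    if slots.n_groups < 2:
        raise ValueError(f"need >= 2 informative respondents for trait {trait!r}")
    observed = delta_from_slots(slots.values, slots)
    if observed >= target_delta:
        return 0.0
    engine = RelocationEngine(slots, np.random.default_rng(seed))
    n_swaps = engine.run_until(0, target_delta)
    return relocated_pct(n_swaps, slots.n_slots)


def stepwise_effect_size(cohort: CohortTable, trait: str, null: NullDistribution,
                         n_runs: int = 10_000, seed: int = 0) -> EffectSizeEstimate:
    """Mean % of partners relocated to reach the null-expected Δ̄, with 95% CI.

    The stopping target is the permutation-null mean for the trait; the CI is
    the 2.5–97.5% quantile band over independent runs.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    target = null.mean
    slots = cohort.trait_slots(trait)
    if slots.n_groups < 2:
        raise ValueError(f"need >= 2 informative respondents for trait {trait!r}")
    observed = delta_from_slots(slots.values, slots)
    if observed >= target:
        pcts = np.zeros(n_runs)
    else:
        child_seeds = np.random.SeedSequence(seed).spawn(n_runs)
        pcts = np.empty(n_runs)
        for i, ss in enumerate(child_seeds):
            engine = RelocationEngine(slots, np.random.default_rng(ss))
            pcts[i] = relocated_pct(engine.run_until(0, target), slots.n_slots)
    lo, hi = np.percentile(pcts, [2.5, 97.5])
    return EffectSizeEstimate(
        trait=trait, effect_pct=float(np.mean(pcts)),
        ci_lo=float(lo), ci_hi=float(hi), n_runs=n_runs, seed=seed,
    )


def minimal_relocation_to_max(cohort: CohortTable, trait: str) -> float:
    """Minimal % of partners relocated to reach the maximal-Δ̄ configuration.

    Deterministic helper for balanced two-level cohorts where every respondent
    has two same-valued partners (e.g. the brown/blue eye-colour toy): pairing
    each homogeneous low-level respondent with a homogeneous high-level one
    and swapping one partner across makes every respondent mixed, which is the
    unique Δ̄-maximal configuration; no smaller relocation set achieves it.
    """
    slots = cohort.trait_slots(trait)
    if not np.all(slots.group_sizes == 2):
        raise ValueError("helper requires exactly two partners per respondent")
    levels = np.unique(slots.values)
    if len(levels) != 2:
        raise ValueError("helper requires a two-level trait")
    pairs = slots.values.reshape(-1, 2)
    lo_pairs = np.flatnonzero((pairs == levels[0]).all(axis=1))
    hi_pairs = np.flatnonzero((pairs == levels[1]).all(axis=1))
    if len(lo_pairs) != len(hi_pairs) or (len(lo_pairs) + len(hi_pairs)) != slots.n_groups:
        raise ValueError("helper requires a balanced all-homogeneous cohort")
    values = slots.values.copy()
    n_swaps = 0
    for g_lo, g_hi in zip(lo_pairs, hi_pairs):
        a = slots.group_offsets[g_lo]       # first partner of the low pair
        b = slots.group_offsets[g_hi]       # first partner of the high pair
        values[[a, b]] = values[[b, a]]
        n_swaps += 1
    achieved = delta_from_slots(values, slots)
    max_delta = float(levels[1] - levels[0])  # every respondent mixed
    if not np.isclose(achieved, max_delta):
        raise RuntimeError("relocation schedule failed to reach the maximal Δ̄")
    return relocated_pct(n_swaps, slots.n_slots)
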