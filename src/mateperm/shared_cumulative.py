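"""Residual, shared and maximal cumulative effect sizes across traits.

Effect sizes measured in "% of partners to relocate" behave like set
measures: if eliminating consistency on trait A already relocates some of
the partners that trait B's consistency depends on, the residual effect of B
after A is smaller than its simple effect. The overlap (shared effect,
A ∩ B) follows from the identity

    E_A + E_B = (A ∩ ¬B) + (B ∩ ¬A) + 2 (A ∩ B) = union + shared,

with the union taken as the mean of the two directed estimates
(E_A + resid(B|A) and E_B + resid(A|B)) and the shared part clamped at zero.

Higher-order intersections are not resampled; they are apportioned
proportionally to the pairwise segments, and traits are accumulated one at a
time by maximal unique contribution into the maximal cumulative effect size
— the % of partners to relocate to remove consistency on all traits at once.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .consistency_core import _null_samples, delta_from_slots
from .stepwise_effect import RelocationEngine, relocated_pct
from .trait_model_io import CohortTable


@dataclass
class SharedEffectTable:
    """Simple effects (diagonal), pairwise shared effects, optional correlations.

    ``shared`` is a symmetric trait × trait DataFrame whose diagonal equals
    ``simple``; off-diagonal entries are clamped into [0, min(E_A, E_B)].
    ``corr`` (optional) carries partner-level Pearson correlations, by
    convention stored in the upper triangle of the combined table-2-shaped CSV.
    """

    simple: pd.Series
    shared: pd.DataFrame
    corr: pd.DataFrame | None = None
    resid: pd.DataFrame | None = None  # resid.loc[a, b] = resid(B=b | A=a)

    def __post_init__(self) -> None:
        t = list(self.simple.index)
        if list(self.shared.index) != t or list(self.shared.columns) != t:
            raise ValueError("shared matrix must be indexed by the same traits")
        s = self.shared.to_numpy(dtype=float)
        if not np.allclose(s, s.T, equal_nan=True):
            raise ValueError("shared matrix must be symmetric")
        if not np.allclose(np.diag(s), self.simple.to_numpy(dtype=float)):
            raise ValueError("diagonal of shared must equal the simple effects")
        cap = np.minimum.outer(self.simple.to_numpy(float), self.simple.to_numpy(float))
        off = ~np.eye(len(t), dtype=bool)
        if np.any(s[off] - cap[off] > 1e-9) or np.any(s[off] < -1e-12):
            raise ValueError("shared effects must lie in [0, min(simple effects)]")

    @property
    def traits(self) -> list[str]:
        return list(self.simple.index)

    # table-2-shaped square CSV: diagonal simple, lower triangle shared,
    # upper triangle correlations (blank if not available)
    def to_csv(self, path: str | Path) -> None:
        t = self.traits
        out = pd.DataFrame(np.nan, index=t, columns=t)
        for i, a in enumerate(t):
            out.loc[a, a] = self.simple[a]
            for b in t[:i]:
                out.loc[a, b] = self.shared.loc[a, b]
            if self.corr is not None:
                for b in t[i + 1:]:
                    out.loc[a, b] = self.corr.loc[a, b]
        out.to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SharedEffectTable":
        """Read a table-2-shaped square CSV.

        Off-diagonal shared effects are clamped into [0, min(simple)]:
        printed/rounded tables can carry tiny overshoots (e.g. a 0.1% shared
        effect against a 0.0% simple effect) that the exact set identity
        forbids.
        """
        raw = pd.read_csv(path, index_col=0)
        t = list(raw.index)
        if list(raw.columns) != t:
            raise ValueError("table must be square with matching trait order")
        simple = pd.Series(np.diag(raw.to_numpy(float)), index=t)
        shared = pd.DataFrame(np.nan, index=t, columns=t)
        corr = pd.DataFrame(np.nan, index=t, columns=t)
        for i, a in enumerate(t):
            shared.loc[a, a] = simple[a]
            for b in t[:i]:
                s = float(raw.loc[a, b])
                s = min(max(s, 0.0), simple[a], simple[b])
                shared.loc[a, b] = shared.loc[b, a] = s
            for b in t[i + 1:]:
                corr.loc[a, b] = corr.loc[b, a] = raw.loc[a, b]
        if corr.isna().all().all():
            corr = None
        return cls(simple=simple, shared=shared, corr=corr)


@dataclass
class CumulativeResult:
    inclusion_order: list[str]
    unique_contributions: list[float]
    total_pct: float


# -- resampled pairwise quantities -----------------------------------------


def _single_trait_view(slots, col: int):
    return replace(slots, values=slots.values[:, col])


def pairwise_effects(cohort: CohortTable, a: str, b: str, n_runs: int = 1_000,
                     n_perm: int = 2_000, seed: int = 0) -> dict[str, float]:
    """Simple and directed residual effects for a trait pair on the
    pairwise-complete partner subset.

    Per run the pair-complete cohort is randomized by whole-partner swaps
    until Δ̄(A) reaches its null mean, then swapping continues against B's
    null mean; only the second leg counts toward resid(B|A). Returns a dict
    with keys ``e_a``, ``e_b``, ``resid_b_given_a``, ``resid_a_given_b``.
    """
    slots = cohort.multi_trait_slots([a, b])
    if slots.n_groups < 2:
        raise ValueError(f"no common informative partners for {a!r} and {b!r}")
    ss = np.random.SeedSequence(seed).spawn(3)
    rng_null = np.random.default_rng(ss[0])
    targets, observed, simple = {}, {}, {}
    for col, trait in enumerate((a, b)):
        view = _single_trait_view(slots, col)
        observed[trait] = delta_from_slots(view.values, view)
        targets[trait] = float(np.mean(_null_samples(view, n_perm, rng_null)))

    def _simple_and_residuals(first: int, second: int, seed_seq) -> tuple[float, float]:
        t_first, t_second = targets[(a, b)[first]], targets[(a, b)[second]]
        child = seed_seq.spawn(n_runs)
        first_pcts = np.empty(n_runs)
        second_pcts = np.empty(n_runs)
        for i, s in enumerate(child):
            engine = RelocationEngine(slots, np.random.default_rng(s))
            k1 = engine.run_until(first, t_first) if engine.delta(first) < t_first else 0
            k2 = engine.run_until(second, t_second) if engine.delta(second) < t_second else 0
            first_pcts[i] = relocated_pct(k1, slots.n_slots)
            second_pcts[i] = relocated_pct(k2, slots.n_slots)
        return float(first_pcts.mean()), float(second_pcts.mean())

    e_a, resid_b_given_a = _simple_and_residuals(0, 1, ss[1])
    e_b, resid_a_given_b = _simple_and_residuals(1, 0, ss[2])
    return {
        "e_a": e_a, "e_b": e_b,
        "resid_b_given_a": resid_b_given_a, "resid_a_given_b": resid_a_given_b,
    }


def residual_effect_size(cohort: CohortTable, a: str, b: str,
                         nulls: Mapping[str, float] | None = None,
                         n_runs: int = 1_000, seed: int = 0) -> float:
    """Mean residual % of partners to relocate for B after eliminating A.

    ``nulls`` may supply precomputed target Δ̄ means per trait (on the
    pair-complete subset); otherwise they are estimated by permutation.
    """
    slots = cohort.multi_trait_slots([a, b])
    if slots.n_groups < 2:
        raise ValueError(f"no common informative partners for {a!r} and {b!r}")
    ss = np.random.SeedSequence(seed).spawn(2)
    if nulls is None:
        rng_null = np.random.default_rng(ss[0])
        nulls = {
            t: float(np.mean(_null_samples(_single_trait_view(slots, c), 2_000, rng_null)))
            for c, t in enumerate((a, b))
        }
    child = ss[1].spawn(n_runs)
    pcts = np.empty(n_runs)
    for i, s in enumerate(child):
        engine = RelocationEngine(slots, np.random.default_rng(s))
        if engine.delta(0) < nulls[a]:
            engine.run_until(0, nulls[a])
        k = engine.run_until(1, nulls[b]) if engine.delta(1) < nulls[b] else 0
        pcts[i] = relocated_pct(k, slots.n_slots)
    return float(pcts.mean())


# -- set algebra -----------------------------------------------------------


def shared_effect(e_a: float, e_b: float, resid_b_given_a: float,
                  resid_a_given_b: float) -> tuple[float, float]:
    """Shared effect A ∩ B and union A ∪ B from the two directed estimates.

    union = mean of the two directed cumulative estimates; shared =
    E_A + E_B − union, clamped at 0 (no negative relationship between
    consistencies is allowed).
    """
    if min(e_a, e_b, resid_b_given_a, resid_a_given_b) < 0:
        raise ValueError("effect sizes must be non-negative")
    union = 0.5 * ((e_a + resid_b_given_a) + (e_b + resid_a_given_b))
    shared = max(e_a + e_b - union, 0.0)
    return shared, union


def apportion_higher_order(e_a: float, e_b: float, e_c: float, shared_ab: float,
                           shared_ac: float, shared_bc: float
                           ) -> tuple[float, float, float, float, float]:
    """Proportional apportionment of a third trait's overlap with A ∪ B.

    The segments (A∩C)¬B, (B∩C)¬A and A∩B∩C are assumed proportional to the
    union's own segments A¬B : B¬A : A∩B and scaled so that, counting
    A∩B∩C twice, they add up to shared_ac + shared_bc. Returns
    (ac_not_b, bc_not_a, abc, unique_c, union_abc).
    """
    if min(shared_ab, shared_ac, shared_bc) < 0:
        raise ValueError("shared effects must be non-negative")
    if shared_ab - min(e_a, e_b) > 1e-9:
        raise ValueError("shared effect cannot exceed either simple effect")
    r = np.array([e_a - shared_ab, e_b - shared_ab, shared_ab], dtype=float)
    r = np.clip(r, 0.0, None)
    denom = r[0] + r[1] + 2.0 * r[2]      # A∩B∩C is double-counted
    total_c_overlap = shared_ac + shared_bc
    if denom <= 0.0:
        segments = np.zeros(3)
    else:
        segments = (total_c_overlap / denom) * r
    ac_not_b, bc_not_a, abc = (float(x) for x in segments)
    unique_c = max(e_c - (ac_not_b + bc_not_a + abc), 0.0)
    union_abc = e_a + (e_b - shared_ab) + unique_c
    return ac_not_b, bc_not_a, abc, unique_c, union_abc


def _overlap_with_union(e_c: float, shared_with_included: float,
                        running_total: float, included_simple_sum: float) -> float:
    """Overlap of a candidate trait with the running union.

    Proportional apportionment over the union's region decomposition reduces
    to two scalars: with W the running union total and M the sum of included
    simple effects (each region's weight counted once per member trait),
    scaling the per-region overlaps by t = Σ shared(X, C) / M gives an
    overlap of t · W.
    """
    if included_simple_sum <= 0.0:
        return 0.0
    t = shared_with_included / included_simple_sum
    return t * running_total


def cumulative_effect(table: SharedEffectTable,
                      order: Sequence[str] | None = None) -> CumulativeResult:
    """Maximal cumulative effect size by stepwise trait accumulation.

    Starts from the largest simple effect and repeatedly adds the trait with
    the largest unique contribution to the running union (ties broken by
    trait name). A candidate's contribution computed at any step caps its
    contribution at all later steps (the minimum rule: a later *increase* in
    apparent unique contribution signals apportionment error, not new
    signal). Contributions are floored at 0. ``order`` forces a fixed
    inclusion sequence instead of the maximal-contribution selection.
    """
    simple = table.simple.astype(float)
    shared = table.shared
    traits = table.traits
    if order is not None:
        if sorted(order) != sorted(traits):
            raise ValueError("order must be a permutation of the table's traits")
    remaining = set(traits)
    included: list[str] = []
    contributions: list[float] = []
    min_seen: dict[str, float] = {t: float("inf") for t in traits}
    W = 0.0  # running union total
    M = 0.0  # sum of included simple effects

    def unique_contribution(c: str) -> float:
        overlap = _overlap_with_union(
            simple[c], sum(shared.loc[x, c] for x in included), W, M
        )
        u = max(simple[c] - overlap, 0.0)
        min_seen[c] = min(min_seen[c], u)
        return min_seen[c]

    step = 0
    while remaining:
        if order is not None:
            pick = order[step]
            contrib = simple[pick] if step == 0 else unique_contribution(pick)
            # keep candidate caps current for traits still to come
            for c in remaining - {pick}:
                if step > 0:
                    unique_contribution(c)
        else:
            if step == 0:
                scored = {c: simple[c] for c in remaining}
            else:
                scored = {c: unique_contribution(c) for c in remaining}
            best = max(scored.values())
            pick = min(c for c, v in scored.items() if v == best)
            contrib = scored[pick]
        included.append(pick)
        contributions.append(float(contrib))
        remaining.discard(pick)
        W += contrib
        M += simple[pick]
        step += 1
    return CumulativeResult(
        inclusion_order=included,
        unique_contributions=contributions,
        total_pct=float(sum(contributions)),
    )


def build_shared_effect_table(cohort: CohortTable,
                              traits: Sequence[str] | None = None,
                              n_runs: int = 1_000, n_perm: int = 2_000,
                              seed: int = 0) -> SharedEffectTable:
    """Resample simple/residual effects for every trait pair and assemble the table."""
    traits = list(traits) if traits is not None else cohort.registry.names
    n = len(traits)
    simple = pd.Series(0.0, index=traits)
    shared = pd.DataFrame(0.0, index=traits, columns=traits)
    resid = pd.DataFrame(np.nan, index=traits, columns=traits)
    ss = np.random.SeedSequence(seed)
    pair_seeds = iter(ss.spawn(n * (n - 1) // 2))
    # pairwise-complete simple effects may differ slightly per pair; the
    # diagonal records the per-trait estimate averaged over its pairings
    simple_sums = {t: [] for t in traits}
    for i, a in enumerate(traits):
        for b in traits[i + 1:]:
            eff = pairwise_effects(cohort, a, b, n_runs=n_runs, n_perm=n_perm,
                                   seed=int(np.random.default_rng(next(pair_seeds)).integers(2**31 - 1)))
            s, _ = shared_effect(eff["e_a"], eff["e_b"],
                                 eff["resid_b_given_a"], eff["resid_a_given_b"])
            s = min(s, eff["e_a"], eff["e_b"])
            shared.loc[a, b] = shared.loc[b, a] = s
            resid.loc[a, b] = eff["resid_b_given_a"]
            resid.loc[b, a] = eff["resid_a_given_b"]
            simple_sums[a].append(eff["e_a"])
            simple_sums[b].append(eff["e_b"])
    for t in traits:
        simple[t] = float(np.mean(simple_sums[t])) if simple_sums[t] else 0.0
        shared.loc[t, t] = simple[t]
    # clamp shared into [0, min(simple)] after diagonal averaging
    for i, a in enumerate(traits):
        for b in traits[i + 1:]:
            s = min(shared.loc[a, b], simple[a], simple[b])
            shared.loc[a, b] = shared.loc[b, a] = max(s, 0.0)
    return SharedEffectTable(simple=simple, shared=shared, resid=resid)
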