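"""Are fathers typical or exceptional among a woman's long-term partners?

Three complementary contrasts per trait:

* exclusion permutation test — how Δ̄ changes when the actual fathers are
  removed from each partner set, against the change when the same number of
  randomly chosen partners per respondent is removed (two-tailed); a change
  below expectation means fathers are exceptional (removing them tightens
  the partner sets), above means they are especially typical;
* mean contrast — random-intercept mixed model of trait on a father
  indicator (respondent identity as random factor);
* variance contrast — the mixed-model analogue of Levene's test: the same
  model on absolute deviations from the father/non-father group mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .trait_model_io import CohortTable, TraitSlots


@dataclass
class FatherExclusionRow:
    trait: str
    observed_change: float
    expected_change_mean: float
    expected_change_sd: float
    p: float
    p_adj: float | None = None


@dataclass
class GroupComparisonRow:
    trait: str
    kind: str  # "mean" or "variance"
    intercept_nonfather: float
    effect_father: float
    se: float
    p: float
    p_adj: float | None = None


# -- exclusion permutation test --------------------------------------------


def _exclusion_deltas(slots: TraitSlots, masks: np.ndarray) -> np.ndarray:
    """Δ̄ over respondents that keep >= 2 partners, for each exclusion mask.

    ``masks`` is (m, n_slots) boolean; each row excludes a fixed number of
    partners per respondent, so the set of qualifying respondents and each
    one's surviving pair count are identical across rows.
    """
    f_per_group = np.add.reduceat(masks[0].astype(np.int64), slots.group_offsets)
    remaining = slots.group_sizes - f_per_group
    qualifying = remaining >= 2
    if not qualifying.any():
        raise ValueError("no respondent remains informative after exclusion")
    diffs = np.abs(slots.values[slots.pair_a] - slots.values[slots.pair_b])
    alive = ~masks[:, slots.pair_a] & ~masks[:, slots.pair_b]
    pair_offsets = np.concatenate([[0], np.cumsum(slots.pairs_per_group)[:-1]])
    sums = np.add.reduceat(alive * diffs, pair_offsets, axis=1)
    denom = remaining * (remaining - 1) // 2
    per_group = sums[:, qualifying] / denom[qualifying]
    return per_group.mean(axis=1)


def father_exclusion_change(cohort: CohortTable, trait: str) -> float:
    """Δ̄ without father-flagged partners minus Δ̄ of the full partner sets.

    Respondents reduced below two informative partners leave the restricted
    average; negative change = fathers were outliers within their sets.
    """
    slots = cohort.trait_slots(trait)
    if not slots.is_father.any():
        raise ValueError(f"no father-flagged informative partner for trait {trait!r}")
    full = _exclusion_deltas(slots, np.zeros((1, slots.n_slots), dtype=bool))[0]
    restricted = _exclusion_deltas(slots, slots.is_father[None, :])[0]
    return float(restricted - full)


def _random_father_masks(slots: TraitSlots, n_perm: int,
                         rng: np.random.Generator) -> np.ndarray:
    """Relabel, per respondent, the observed number of fathers at random."""
    masks = np.zeros((n_perm, slots.n_slots), dtype=bool)
    for off, p in zip(slots.group_offsets, slots.group_sizes):
        f = int(slots.is_father[off:off + p].sum())
        if f == 0:
            continue
        keys = rng.random((n_perm, p))
        chosen = np.argpartition(keys, f - 1, axis=1)[:, :f]
        masks[np.arange(n_perm)[:, None], off + chosen] = True
    return masks


def father_exclusion_test(cohort: CohortTable, trait: str, n_perm: int = 10_000,
                          seed: int = 0) -> FatherExclusionRow:
    """Two-tailed permutation test of the father-exclusion change in Δ̄.

    Each permutation relabels within every respondent the same number of
    partners as fathers uniformly at random, excludes them, and recomputes
    the change; p = 2 · min(frac ≤ observed, frac ≥ observed), capped at 1.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    slots = cohort.trait_slots(trait)
    if not slots.is_father.any():
        raise ValueError(f"no father-flagged informative partner for trait {trait!r}")
    full = _exclusion_deltas(slots, np.zeros((1, slots.n_slots), dtype=bool))[0]
    observed = _exclusion_deltas(slots, slots.is_father[None, :])[0] - full
    rng = np.random.default_rng(seed)
    masks = _random_father_masks(slots, n_perm, rng)
    changes = _exclusion_deltas(slots, masks) - full
    lo = float(np.mean(changes <= observed))
    hi = float(np.mean(changes >= observed))
    return FatherExclusionRow(
        trait=trait,
        observed_change=float(observed),
        expected_change_mean=float(changes.mean()),
        expected_change_sd=float(changes.std(ddof=1)) if n_perm > 1 else 0.0,
        p=min(1.0, 2.0 * min(lo, hi)),
    )


# -- mixed-model group contrasts -------------------------------------------


def _father_mixed_model(df: pd.DataFrame, trait: str, response: np.ndarray,
                        kind: str) -> GroupComparisonRow:
    groups = df["respondent_id"].to_numpy()
    exog = sm.add_constant(df["is_father"].to_numpy(dtype=float))
    if np.ptp(response) == 0:
        raise ValueError(f"trait {trait!r}: degenerate (constant) response, inestimable")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.MixedLM(response, exog, groups=groups).fit(reml=True)
        except Exception as err:  # noqa: BLE001
            raise RuntimeError(f"mixed model failed to converge for {trait!r}") from err
    return GroupComparisonRow(
        trait=trait, kind=kind,
        intercept_nonfather=float(fit.params[0]),
        effect_father=float(fit.params[1]),
        se=float(fit.bse[1]),
        p=float(fit.pvalues[1]),
    )


def group_mean_model(cohort: CohortTable, trait: str) -> GroupComparisonRow:
    """Father vs non-father mean contrast (random respondent intercept, REML)."""
    df = cohort.df.dropna(subset=[trait])
    if df["is_father"].nunique() < 2:
        raise ValueError(f"trait {trait!r}: need both father and non-father values")
    return _father_mixed_model(df, trait, df[trait].to_numpy(dtype=float), "mean")


def group_variance_model(cohort: CohortTable, trait: str) -> GroupComparisonRow:
    """Levene-style variance contrast: |value − its group mean| as response.

    Group means are global father/non-father means, so the father effect
    measures whether father values spread more widely around their own
    group's centre.
    """
    df = cohort.df.dropna(subset=[trait])
    by_group = df.groupby("is_father")[trait]
    if len(by_group) < 2 or (by_group.size() < 2).any():
        raise ValueError(f"trait {trait!r}: both groups need >= 2 values")
    centred = (df[trait] - by_group.transform("mean")).abs().to_numpy(dtype=float)
    return _father_mixed_model(df, trait, centred, "variance")


def father_contrast_tables(cohort: CohortTable, traits=None, n_perm: int = 10_000,
                           seed: int = 0
                           ) -> tuple[list[FatherExclusionRow], list[GroupComparisonRow]]:
    """All three father contrasts for each trait, BH-adjusted per 21-trait family."""
    from .association_measures import bh_adjust

    traits = list(traits) if traits is not None else cohort.registry.names
    rng = np.random.default_rng(seed)
    excl = [
        father_exclusion_test(cohort, t, n_perm=n_perm,
                              seed=int(rng.integers(2**31 - 1)))
        for t in traits
    ]

    def _try_model(fn, t, kind):
        # inestimable (e.g. constant) traits stay in the table as NaN rows
        try:
            return fn(cohort, t)
        except (ValueError, RuntimeError):
            nan = float("nan")
            return GroupComparisonRow(trait=t, kind=kind, intercept_nonfather=nan,
                                      effect_father=nan, se=nan, p=nan)

    means = [_try_model(group_mean_model, t, "mean") for t in traits]
    variances = [_try_model(group_variance_model, t, "variance") for t in traits]
    # BH separately per family of tests; NaN p-values sit out the adjustment
    for family in (excl, means, variances):
        estimable = [r for r in family if np.isfinite(r.p)]
        adj = bh_adjust([r.p for r in estimable]) if estimable else []
        for r, a in zip(estimable, adj):
            r.p_adj = float(a)
    return excl, means + variances
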