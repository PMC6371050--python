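"""Correlational consistency measures and their equivalence to relocation effects.

Two non-permutation measures of mate-choice consistency are computed per
trait: the share of partner-trait variance attributable to respondent
identity (the ICC from a random-intercept mixed model; benchmarks 10% =
meaningful, 20% = medium, 30% = large) and a double-entry Pearson r over all
within-respondent partner pairs. The equivalence analysis correlates these
with the relocation effect size across traits and fits the OLS line of
ICC% on effect%, and partner-level trait correlations are screened with
Benjamini–Hochberg control.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .trait_model_io import CohortTable

#: Interpretation benchmarks for respondent-attributable variance.
ICC_BENCHMARKS = {"meaningful": 10.0, "medium": 20.0, "large": 30.0}


@dataclass
class AssociationRow:
    trait: str
    icc_pct: float
    pearson_r: float
    n_pairs: int
    icc_label: str = ""


@dataclass
class EquivalenceSummary:
    corr_effect_icc: float
    corr_effect_r: float
    corr_icc_r: float
    slope: float
    slope_ci: tuple[float, float]
    intercept: float
    intercept_ci: tuple[float, float]


def icc_label(icc_pct: float) -> str:
    if icc_pct >= ICC_BENCHMARKS["large"]:
        return "large"
    if icc_pct >= ICC_BENCHMARKS["medium"]:
        return "medium"
    if icc_pct >= ICC_BENCHMARKS["meaningful"]:
        return "meaningful"
    return "negligible"


def icc_percent(cohort: CohortTable, trait: str) -> float:
    """Respondent-attributable variance % from a REML random-intercept model.

    Fits partner trait value with respondent identity as the sole random
    factor and returns 100 · var(respondent) / (var(respondent) + var(residual)).
    Singular fits yield the boundary estimate 0.
    """
    slots = cohort.trait_slots(trait)
    if slots.n_groups < 2:
        raise ValueError(f"need >= 2 informative respondents for trait {trait!r}")
    values = slots.values
    groups = np.repeat(np.arange(slots.n_groups), slots.group_sizes)
    if np.ptp(values) == 0:
        return 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(values, np.ones((len(values), 1)), groups=groups)
        try:
            fit = model.fit(reml=True)
        except Exception as err:  # noqa: BLE001 - surfaced with trait context
            raise RuntimeError(f"mixed model failed to converge for {trait!r}") from err
    var_u = float(np.asarray(fit.cov_re)[0, 0])
    var_e = float(fit.scale)
    if var_u + var_e <= 0:
        return 0.0
    return 100.0 * var_u / (var_u + var_e)


def pairwise_pearson(cohort: CohortTable, trait: str) -> float:
    """Double-entry Pearson r over all within-respondent partner pairs.

    Every unordered pair of a respondent's partners enters in both
    orientations, which makes the coefficient symmetric. Respondents with
    more partners contribute more pairs (no reweighting).
    """
    slots = cohort.trait_slots(trait)
    if slots.n_groups < 2:
        raise ValueError(f"need >= 2 informative respondents for trait {trait!r}")
    x = slots.values[slots.pair_a]
    y = slots.values[slots.pair_b]
    xx = np.concatenate([x, y])
    yy = np.concatenate([y, x])
    if np.ptp(xx) == 0 or np.ptp(yy) == 0:
        raise ValueError(f"zero variance in partner pairs for trait {trait!r}")
    return float(np.corrcoef(xx, yy)[0, 1])


def association_table(cohort: CohortTable,
                      traits: Sequence[str] | None = None) -> list[AssociationRow]:
    traits = list(traits) if traits is not None else cohort.registry.names
    rows = []
    for trait in traits:
        slots = cohort.trait_slots(trait)
        icc = icc_percent(cohort, trait)
        try:
            r = pairwise_pearson(cohort, trait)
        except ValueError:
            r = float("nan")
        rows.append(AssociationRow(
            trait=trait, icc_pct=icc, pearson_r=r,
            n_pairs=int(slots.pairs_per_group.sum()), icc_label=icc_label(icc),
        ))
    return rows


def measure_equivalence(rows: pd.DataFrame) -> EquivalenceSummary:
    """Cross-trait agreement of the three effect-size measures.

    ``rows`` needs columns effect_pct, icc_pct, pearson_r (one row per
    trait). Returns the three pairwise Pearson correlations and the OLS fit
    of icc_pct on effect_pct with 95% CIs.
    """
    needed = {"effect_pct", "icc_pct", "pearson_r"}
    if not needed.issubset(rows.columns):
        raise ValueError(f"rows must have columns {sorted(needed)}")
    if len(rows) < 3:
        raise ValueError("need at least 3 traits")
    e = rows["effect_pct"].to_numpy(float)
    icc = rows["icc_pct"].to_numpy(float)
    r = rows["pearson_r"].to_numpy(float)
    for name, v in (("effect_pct", e), ("icc_pct", icc), ("pearson_r", r)):
        if np.ptp(v) == 0:
            raise ValueError(f"column {name} is constant")
    fit = sm.OLS(icc, sm.add_constant(e)).fit()
    ci = fit.conf_int(alpha=0.05)
    return EquivalenceSummary(
        corr_effect_icc=float(np.corrcoef(e, icc)[0, 1]),
        corr_effect_r=float(np.corrcoef(e, r)[0, 1]),
        corr_icc_r=float(np.corrcoef(icc, r)[0, 1]),
        slope=float(fit.params[1]),
        slope_ci=(float(ci[1][0]), float(ci[1][1])),
        intercept=float(fit.params[0]),
        intercept_ci=(float(ci[0][0]), float(ci[0][1])),
    )


def trait_correlations(cohort: CohortTable,
                       traits: Sequence[str] | None = None,
                       alpha: float = 0.05
                       ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Partner-level Pearson correlations for all trait pairs with BH flags.

    Uses pairwise-complete partners per pair; p-values are two-sided and BH-
    adjusted jointly across all pairs. Pairs with fewer than 3 complete
    observations stay missing. Returns (r, p_adj, significant) DataFrames.
    """
    traits = list(traits) if traits is not None else cohort.registry.names
    if len(traits) < 2:
        raise ValueError("need >= 2 traits")
    df = cohort.df
    n = len(traits)
    r = pd.DataFrame(np.eye(n), index=traits, columns=traits)
    p = pd.DataFrame(np.nan, index=traits, columns=traits)
    pairs, pvals = [], []
    for a, b in itertools.combinations(traits, 2):
        sub = df[[a, b]].dropna()
        if len(sub) < 3 or sub[a].nunique() < 2 or sub[b].nunique() < 2:
            r.loc[a, b] = r.loc[b, a] = np.nan
            continue
        res = scipy.stats.pearsonr(sub[a], sub[b])
        r.loc[a, b] = r.loc[b, a] = float(res.statistic)
        pairs.append((a, b))
        pvals.append(float(res.pvalue))
    adj = bh_adjust(pvals) if pvals else []
    for (a, b), q in zip(pairs, adj):
        p.loc[a, b] = p.loc[b, a] = q
    sig = p < alpha
    return r, p, sig


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
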