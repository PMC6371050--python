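import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import random_cohort
from mateperm.association_measures import (bh_adjust, icc_percent,
                                           measure_equivalence,
                                           pairwise_pearson,
                                           trait_correlations)
from mateperm.reference import consistency_summary
from mateperm.synthetic_cohort import SyntheticConfig, generate_cohort
from mateperm.trait_model_io import CohortTable, TraitRegistry, TraitSpec


# -- ICC -------------------------------------------------------------------


def test_icc_near_100_when_all_variance_between(three_pair_cohort):
    # partners identical within respondents, 2/5/8 across respondents
    assert icc_percent(three_pair_cohort, "extraversion") > 95.0


def test_icc_near_zero_for_iid_values():
    cohort = random_cohort(60, seed=8)
    assert icc_percent(cohort, "extraversion") < 10.0


@pytest.mark.parametrize("true_icc", [0.1, 0.2, 0.3])
def test_icc_parameter_recovery(true_icc):
    reg = TraitRegistry([TraitSpec("t", "physical", 40, 200)])
    errors = []
    for seed in range(10):
        cfg = SyntheticConfig(n_respondents=500, registry=reg, icc=true_icc,
                              missing_rate=0.0, seed=seed)
        cohort, truth = generate_cohort(cfg)
        est = icc_percent(cohort, "t")
        errors.append(est - 100 * truth.icc["t"])
    # the recovery estimate (mean across seeds) is what must land within
    # +/-5 points; single seeds carry ~3-point sampling error
    assert abs(np.mean(errors)) < 5.0
    assert np.max(np.abs(errors)) < 10.0


def test_icc_constant_trait_is_boundary_zero(three_pair_cohort):
    df = three_pair_cohort.df.copy()
    df["extraversion"] = 5.0
    cohort = CohortTable(df, three_pair_cohort.registry)
    assert icc_percent(cohort, "extraversion") == 0.0


# -- double-entry pairwise r ----------------------------------------------


def test_pairwise_r_one_when_partners_identical(three_pair_cohort):
    assert pairwise_pearson(three_pair_cohort, "extraversion") == pytest.approx(1.0)


def test_pairwise_r_near_zero_for_iid_values():
    cohort = random_cohort(200, seed=9)
    assert abs(pairwise_pearson(cohort, "extraversion")) < 0.12


def test_pairwise_r_matches_bruteforce_double_entry():
    cohort = random_cohort(3, seed=10)
    df = cohort.df
    xs, ys = [], []
    for _, grp in df.groupby("respondent_id"):
        vals = grp["extraversion"].tolist()
        for a, b in itertools.combinations(vals, 2):
            xs += [a, b]
            ys += [b, a]
    expected = np.corrcoef(xs, ys)[0, 1]
    assert pairwise_pearson(cohort, "extraversion") == pytest.approx(expected)


def test_pairwise_r_zero_variance_raises(three_pair_cohort):
    df = three_pair_cohort.df.copy()
    df["extraversion"] = 5.0
    cohort = CohortTable(df, three_pair_cohort.registry)
    with pytest.raises(ValueError, match="zero variance"):
        pairwise_pearson(cohort, "extraversion")


def test_measures_rank_traits_concordantly():
    """ICC and double-entry r order 8 traits of varying true ICC alike."""
    from scipy.stats import spearmanr

    names = [f"t{k}" for k in range(8)]
    iccs = {n: 0.05 + 0.05 * k for k, n in enumerate(names)}
    reg = TraitRegistry([TraitSpec(n, "physical", 40, 200) for n in names])
    cfg = SyntheticConfig(n_respondents=250, registry=reg, icc=iccs,
                          missing_rate=0.0, seed=21)
    cohort, _ = generate_cohort(cfg)
    icc_est = [icc_percent(cohort, n) for n in names]
    r_est = [pairwise_pearson(cohort, n) for n in names]
    rho_icc = spearmanr(list(iccs.values()), icc_est).statistic
    rho_r = spearmanr(list(iccs.values()), r_est).statistic
    assert rho_icc >= 0.8 and rho_r >= 0.8


# -- equivalence of the three effect-size measures -------------------------


def test_equivalence_exact_linear_construction():
    rows = pd.DataFrame({
        "effect_pct": [5.0, 10.0, 15.0, 20.0],
        "icc_pct": [10.0, 20.0, 30.0, 40.0],
        "pearson_r": [0.05, 0.1, 0.15, 0.2],
    })
    eq = measure_equivalence(rows)
    assert eq.slope == pytest.approx(2.0)
    assert eq.corr_effect_icc == pytest.approx(1.0)
    assert eq.intercept == pytest.approx(0.0, abs=1e-9)


def test_equivalence_on_reference_summary():
    eq = measure_equivalence(consistency_summary())
    assert eq.corr_effect_icc == pytest.approx(0.93, abs=0.01)
    assert eq.slope == pytest.approx(2.08, abs=0.02)
    assert eq.slope_ci[0] < 2.08 < eq.slope_ci[1]
    assert eq.intercept == pytest.approx(-0.18, abs=0.05)


def test_equivalence_needs_three_traits():
    rows = pd.DataFrame({"effect_pct": [1, 2], "icc_pct": [1, 2],
                         "pearson_r": [0.1, 0.2]})
    with pytest.raises(ValueError):
        measure_equivalence(rows)


# -- partner-level trait correlations --------------------------------------


def test_trait_correlation_pair_count():
    # 21 traits -> 210 unordered pairs
    assert len(list(itertools.combinations(range(21), 2))) == 210


def test_duplicated_trait_flagged_significant():
    reg = TraitRegistry([TraitSpec("a", "physical", 40, 200),
                         TraitSpec("b", "physical", 40, 200)])
    cfg = SyntheticConfig(n_respondents=40, registry=reg, missing_rate=0.0, seed=1)
    cohort, _ = generate_cohort(cfg)
    cohort.df["b"] = cohort.df["a"]
    r, p_adj, sig = trait_correlations(cohort)
    assert r.loc["a", "b"] == pytest.approx(1.0)
    assert bool(sig.loc["a", "b"])


def test_independent_traits_false_positive_rate_controlled():
    names = [f"t{k}" for k in range(5)]  # 10 pairs per replicate
    reg = TraitRegistry([TraitSpec(n, "physical", 40, 200) for n in names])
    flagged, total = 0, 0
    for seed in range(50):
        cfg = SyntheticConfig(n_respondents=50, registry=reg, icc=0.0,
                              missing_rate=0.0, seed=seed)
        cohort, _ = generate_cohort(cfg)
        _, _, sig = trait_correlations(cohort)
        vals = sig.to_numpy()[np.triu_indices(len(names), k=1)]
        flagged += int(vals.sum())
        total += len(vals)
    rate = flagged / total
    # BH controls FDR at 0.05; allow binomial slack
    assert rate <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / total)


# -- Benjamini–Hochberg ----------------------------------------------------


def bh_bruteforce(pvals):
    """Direct step-up definition applied to sorted values."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj_sorted = np.empty(m)
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, p[i] * m / rank)
        adj_sorted[rank - 1] = running_min
    out = np.empty(m)
    out[order] = adj_sorted
    return np.minimum(out, 1.0)


def test_bh_trivial_cases():
    assert bh_adjust([0.05]) == pytest.approx([0.05])
    assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)


@given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
@settings(derandomize=True, max_examples=60)
def test_bh_matches_bruteforce_and_properties(pvals):
    adj = bh_adjust(pvals)
    assert adj == pytest.approx(bh_bruteforce(pvals), abs=1e-12)
    assert np.all(adj >= np.asarray(pvals) - 1e-12)
    assert np.all(adj <= 1.0)
    order = np.argsort(pvals)
    assert np.all(np.diff(adj[order]) >= -1e-12)


def test_bh_rejects_invalid_pvalues():
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.2])
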