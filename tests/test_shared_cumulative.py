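import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mateperm.reference import shared_effect_reference
from mateperm.shared_cumulative import (SharedEffectTable, apportion_higher_order,
                                        cumulative_effect, pairwise_effects,
                                        residual_effect_size, shared_effect)
from mateperm.synthetic_cohort import SyntheticConfig, generate_cohort
from mateperm.trait_model_io import TraitRegistry, TraitSpec


def make_table(traits, simple, shared_off):
    simple = pd.Series(simple, index=traits, dtype=float)
    shared = pd.DataFrame(0.0, index=traits, columns=traits)
    for t in traits:
        shared.loc[t, t] = simple[t]
    for (a, b), v in shared_off.items():
        shared.loc[a, b] = shared.loc[b, a] = v
    return SharedEffectTable(simple=simple, shared=shared)


# -- shared effect identity ------------------------------------------------


def test_shared_effect_worked_example():
    # weight/height illustration: 16% + 6% one way, 11% + 11% the other
    shared, union = shared_effect(16, 11, 6, 11)
    assert shared == pytest.approx(5.0)
    assert union == pytest.approx(22.0)


def test_shared_effect_full_independence_and_clamp():
    shared, union = shared_effect(16, 11, 11, 16)
    assert shared == 0.0 and union == pytest.approx(27.0)
    shared, union = shared_effect(10, 10, 12, 12)
    assert shared == 0.0 and union == pytest.approx(22.0)


@given(e_a=st.floats(0, 50), e_b=st.floats(0, 50),
       r_ba=st.floats(0, 50), r_ab=st.floats(0, 50))
@settings(derandomize=True, max_examples=50)
def test_shared_effect_symmetry(e_a, e_b, r_ba, r_ab):
    s1, u1 = shared_effect(e_a, e_b, r_ba, r_ab)
    s2, u2 = shared_effect(e_b, e_a, r_ab, r_ba)
    assert s1 == pytest.approx(s2) and u1 == pytest.approx(u2)
    assert s1 >= 0.0


# -- proportional apportionment --------------------------------------------


def test_apportionment_worked_example():
    ac_not_b, bc_not_a, abc, unique_c, union = apportion_higher_order(
        20, 15, 10, 10, 4, 3)
    assert (ac_not_b, bc_not_a, abc) == pytest.approx((2.0, 1.0, 2.0))
    assert unique_c == pytest.approx(5.0)
    assert union == pytest.approx(30.0)


def test_apportionment_disjoint_sets():
    *_, unique_c, union = apportion_higher_order(20, 15, 10, 0, 0, 0)
    assert unique_c == pytest.approx(10.0)
    assert union == pytest.approx(45.0)


def test_apportionment_identical_ab():
    # A == B: segment ratio collapses to (0 : 0 : 1), so A∩B∩C carries the
    # whole double-counted overlap
    ac_not_b, bc_not_a, abc, _, _ = apportion_higher_order(12, 12, 8, 12, 4, 4)
    assert ac_not_b == 0.0 and bc_not_a == 0.0
    assert abc == pytest.approx((4 + 4) / 2)


def test_apportionment_rejects_inconsistent_input():
    with pytest.raises(ValueError):
        apportion_higher_order(5, 5, 5, 8, 1, 1)  # shared_ab > simple effects


# -- cumulative accumulation -----------------------------------------------


def naive_cumulative(simple: dict, shared: dict, order=None):
    """Independent from-scratch reimplementation of the accumulation rules.

    Rules: start from the largest simple effect (lexicographic ties); score
    each candidate as its simple effect minus the proportional-apportionment
    overlap with the running union, floored at 0; a candidate's score is
    capped by the minimum score it received at any earlier step; include the
    best-scoring candidate; total = sum of included contributions.
    """
    names = sorted(simple)
    history = {c: [] for c in names}
    included, contribs = [], []
    while len(included) < len(names):
        rest = [c for c in names if c not in included]
        if not included:
            top = max(simple[c] for c in rest)
            best = sorted(c for c in rest if simple[c] == top)[0]
            score = simple[best]
        else:
            m_sum = sum(simple[x] for x in included)
            w_sum = sum(contribs)
            scores = {}
            for c in rest:
                overlap_basis = sum(shared[frozenset((x, c))] for x in included)
                overlap = (overlap_basis / m_sum) * w_sum if m_sum > 0 else 0.0
                raw = max(simple[c] - overlap, 0.0)
                history[c].append(raw)
                scores[c] = min(history[c])
            top = max(scores.values())
            best = sorted([c for c, v in scores.items() if v == top])[0]
            score = scores[best]
        included.append(best)
        contribs.append(score)
    return included, sum(contribs)


def test_cumulative_three_trait_example_fixed_order():
    table = make_table(["A", "B", "C"], {"A": 20, "B": 15, "C": 10},
                       {("A", "B"): 10, ("A", "C"): 4, ("B", "C"): 3})
    res = cumulative_effect(table, order=["A", "B", "C"])
    assert res.unique_contributions == pytest.approx([20, 5, 5])
    assert res.total_pct == pytest.approx(30.0)


def test_cumulative_three_trait_example_greedy_selection():
    # greedy maximal-unique-contribution picks C (unique 6) before B (5)
    table = make_table(["A", "B", "C"], {"A": 20, "B": 15, "C": 10},
                       {("A", "B"): 10, ("A", "C"): 4, ("B", "C"): 3})
    res = cumulative_effect(table)
    assert res.inclusion_order == ["A", "C", "B"]
    oracle_order, oracle_total = naive_cumulative(
        {"A": 20, "B": 15, "C": 10},
        {frozenset(("A", "B")): 10, frozenset(("A", "C")): 4, frozenset(("B", "C")): 3})
    assert res.inclusion_order == oracle_order
    assert res.total_pct == pytest.approx(oracle_total)


def test_cumulative_no_sharing_sums_simple_effects():
    table = make_table(["A", "B", "C", "D"], {"A": 8, "B": 6, "C": 4, "D": 2}, {})
    res = cumulative_effect(table)
    assert res.total_pct == pytest.approx(20.0)
    assert res.unique_contributions == pytest.approx([8, 6, 4, 2])


@pytest.mark.parametrize("seed", range(6))
def test_cumulative_matches_naive_oracle_on_random_instances(seed):
    rng = np.random.default_rng(seed)
    names = ["t1", "t2", "t3", "t4"]
    simple = {c: float(rng.uniform(1, 25)) for c in names}
    shared = {}
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            cap = min(simple[a], simple[b])
            shared[frozenset((a, b))] = float(rng.uniform(0, cap))
    table = make_table(names, simple,
                       {(a, b): shared[frozenset((a, b))]
                        for i, a in enumerate(names) for b in names[i + 1:]})
    res = cumulative_effect(table)
    oracle_order, oracle_total = naive_cumulative(simple, shared)
    assert res.inclusion_order == oracle_order
    assert res.total_pct == pytest.approx(oracle_total)
    assert max(simple.values()) <= res.total_pct <= sum(simple.values()) + 1e-9


def test_cumulative_invariant_to_table_trait_ordering():
    names = ["a", "b", "c", "d"]
    rng = np.random.default_rng(99)
    simple = {c: float(rng.uniform(1, 20)) for c in names}
    off = {}
    for i, x in enumerate(names):
        for y in names[i + 1:]:
            off[(x, y)] = float(rng.uniform(0, min(simple[x], simple[y])))
    t1 = make_table(names, simple, off)
    rev = names[::-1]
    t2 = make_table(rev, {c: simple[c] for c in rev},
                    {(y, x): v for (x, y), v in off.items()})
    r1, r2 = cumulative_effect(t1), cumulative_effect(t2)
    assert r1.total_pct == pytest.approx(r2.total_pct)
    assert r1.inclusion_order == r2.inclusion_order


def test_cumulative_contributions_non_increasing_with_min_rule():
    ref = shared_effect_reference()
    res = cumulative_effect(ref)
    # once the min-replacement cap engages, a trait's effective contribution
    # can never grow; check global sanity of the per-step sequence tail
    contribs = res.unique_contributions
    assert all(c >= 0 for c in contribs)
    assert contribs[0] == pytest.approx(max(ref.simple))


def test_cumulative_bounds_on_reference_inputs():
    ref = shared_effect_reference()
    res = cumulative_effect(ref)
    assert max(ref.simple) < res.total_pct < sum(ref.simple)
    assert res.total_pct == pytest.approx(sum(res.unique_contributions))


# -- table container -------------------------------------------------------


def test_shared_table_roundtrip(tmp_path):
    table = make_table(["A", "B", "C"], {"A": 20, "B": 15, "C": 10},
                       {("A", "B"): 10, ("A", "C"): 4, ("B", "C"): 3})
    path = tmp_path / "t2.csv"
    table.to_csv(path)
    back = SharedEffectTable.from_csv(path)
    pd.testing.assert_series_equal(back.simple, table.simple)
    pd.testing.assert_frame_equal(back.shared, table.shared)


def test_shared_table_rejects_asymmetry():
    simple = pd.Series({"A": 5.0, "B": 5.0})
    bad = pd.DataFrame([[5.0, 2.0], [3.0, 5.0]], index=["A", "B"], columns=["A", "B"])
    with pytest.raises(ValueError, match="symmetric"):
        SharedEffectTable(simple=simple, shared=bad)


def test_reference_table_invariants():
    ref = shared_effect_reference()
    s = ref.shared.to_numpy()
    assert np.allclose(s, s.T)
    cap = np.minimum.outer(ref.simple.to_numpy(), ref.simple.to_numpy())
    off = ~np.eye(len(ref.traits), dtype=bool)
    assert np.all(s[off] <= cap[off] + 1e-9) and np.all(s[off] >= 0)


# -- resampled residual effects --------------------------------------------


def two_trait_cohort(icc_a, icc_b, n=60, seed=0, duplicate=False):
    reg = TraitRegistry([TraitSpec("a", "physical", 40, 200),
                         TraitSpec("b", "physical", 40, 200)])
    cfg = SyntheticConfig(n_respondents=n, registry=reg, missing_rate=0.0,
                          icc={"a": icc_a, "b": icc_b}, seed=seed)
    cohort, _ = generate_cohort(cfg)
    if duplicate:
        cohort.df["b"] = cohort.df["a"]
    return cohort


def test_residual_of_duplicated_trait_is_near_zero():
    cohort = two_trait_cohort(0.4, 0.4, duplicate=True, seed=3)
    resid = residual_effect_size(cohort, "a", "b", n_runs=30, seed=1)
    eff = pairwise_effects(cohort, "a", "b", n_runs=30, n_perm=400, seed=2)
    assert eff["e_b"] > 5.0          # the trait alone has a real effect
    assert resid < 0.25 * eff["e_b"]  # almost all of it removed with A


def test_residual_after_null_trait_matches_simple_effect():
    # a has no consistency (ICC 0): eliminating it removes nothing from b
    cohort = two_trait_cohort(0.0, 0.4, seed=4)
    eff = pairwise_effects(cohort, "a", "b", n_runs=40, n_perm=400, seed=5)
    assert eff["e_a"] < 4.0
    assert eff["resid_b_given_a"] == pytest.approx(eff["e_b"], abs=4.0)


def test_independent_traits_share_little():
    cohort = two_trait_cohort(0.35, 0.35, seed=6)
    eff = pairwise_effects(cohort, "a", "b", n_runs=40, n_perm=400, seed=7)
    s, union = shared_effect(eff["e_a"], eff["e_b"],
                             eff["resid_b_given_a"], eff["resid_a_given_b"])
    assert s <= 0.35 * min(eff["e_a"], eff["e_b"]) + 1.0
    assert union <= eff["e_a"] + eff["e_b"] + 1e-9
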