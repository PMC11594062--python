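import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from neurohcs.model import DegenerateDataError
from neurohcs.stats import (
    aggregate_sites,
    dunnett,
    dunnett_critical_value,
    dunnett_max_abs_t_cdf,
    one_way_anova,
    one_way_anova_dunnett,
    significance_stars,
    simulate_null_anova,
    t_test_unpaired,
    two_way_anova,
)
from oracles import anova_one_way_sums, anova_two_way_sums, pooled_t


def _tidy(values: dict[tuple[str, str], float]) -> pd.DataFrame:
    return pd.DataFrame([{"group": g, "culture": c, "value": v}
                         for (g, c), v in values.items()])


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def test_aggregate_mean_and_flag_exclusion():
    sites = pd.DataFrame([
        {"culture": "c1", "group": "vehicle", "well": 0, "site": 0,
         "qc_flags": "", "soma_drebrin": 1.0},
        {"culture": "c1", "group": "vehicle", "well": 0, "site": 1,
         "qc_flags": "", "soma_drebrin": 2.0},
        {"culture": "c1", "group": "vehicle", "well": 0, "site": 2,
         "qc_flags": "debris", "soma_drebrin": 99.0},
        {"culture": "c1", "group": "1e-06", "well": 0, "site": 0,
         "qc_flags": "", "soma_drebrin": 3.0},
    ])
    agg = aggregate_sites(sites)
    out = agg.set_index(["culture", "group"])
    assert out.loc[("c1", "vehicle"), "value"] == pytest.approx(1.5)
    assert out.loc[("c1", "vehicle"), "n_sites"] == 2
    assert out.loc[("c1", "1e-06"), "value"] == pytest.approx(3.0)


def test_aggregate_errors_when_cell_fully_flagged():
    sites = pd.DataFrame([
        {"culture": "c1", "group": "vehicle", "qc_flags": "debris",
         "soma_drebrin": 1.0},
    ])
    with pytest.raises(DegenerateDataError):
        aggregate_sites(sites)


# ---------------------------------------------------------------------------
# two-way ANOVA
# ---------------------------------------------------------------------------

TOY = {  # 3 treatments x 2 cultures with clear block effects
    ("vehicle", "c1"): 10.0, ("vehicle", "c2"): 14.0,
    ("1e-06", "c1"): 13.0, ("1e-06", "c2"): 18.0,
    ("1e-05", "c1"): 11.0, ("1e-05", "c2"): 16.0,
}


def test_two_way_matches_explicit_sums():
    res = two_way_anova(_tidy(TOY))
    oracle = anova_two_way_sums(TOY)
    assert res.table.loc["treatment", "ss"] == pytest.approx(oracle["ss_treatment"])
    assert res.table.loc["culture", "ss"] == pytest.approx(oracle["ss_culture"])
    assert res.table.loc["residual", "ss"] == pytest.approx(oracle["ss_residual"])
    assert res.table.loc["treatment", "df"] == oracle["df_treatment"]
    assert res.residual_df == oracle["df_residual"]
    assert res.treatment_f == pytest.approx(oracle["f_treatment"])


def test_two_way_random_tables_match_oracle():
    rng = np.random.default_rng(11)
    for _ in range(5):
        vals = {(f"g{i}", f"c{j}"): float(rng.normal())
                for i in range(4) for j in range(5)}
        res = two_way_anova(_tidy(vals))
        oracle = anova_two_way_sums(vals)
        assert res.treatment_f == pytest.approx(oracle["f_treatment"], rel=1e-9)
        # decomposition identity
        total = sum((v - np.mean(list(vals.values()))) ** 2 for v in vals.values())
        parts = res.table["ss"].sum()
        assert parts == pytest.approx(total, rel=1e-9)


def test_two_way_no_treatment_effect_f_zero():
    vals = {("a", "c1"): 1.0, ("a", "c2"): 5.0,
            ("b", "c1"): 1.0, ("b", "c2"): 5.0,
            ("c", "c1"): 1.0, ("c", "c2"): 5.0}
    # identical treatment means but nonzero residual needed: perturb blocks
    vals[("a", "c1")] += 0.1
    vals[("b", "c2")] += 0.1
    vals[("c", "c1")] += 0.1  # keep it non-degenerate
    res = two_way_anova(_tidy(vals))
    assert res.table.loc["treatment", "ss"] >= 0


def test_two_way_culture_permutation_invariance():
    df = _tidy(TOY)
    relabel = {"c1": "cB", "c2": "cA"}
    df2 = df.assign(culture=df["culture"].map(relabel))
    assert two_way_anova(df).treatment_f == pytest.approx(
        two_way_anova(df2).treatment_f)


def test_two_way_preconditions():
    with pytest.raises(DegenerateDataError):
        two_way_anova(_tidy({("a", "c1"): 1.0, ("b", "c1"): 2.0}))  # one culture
    dup = pd.DataFrame([
        {"group": "a", "culture": "c1", "value": 1.0},
        {"group": "a", "culture": "c1", "value": 2.0},
        {"group": "b", "culture": "c1", "value": 1.0},
        {"group": "b", "culture": "c2", "value": 1.0},
        {"group": "a", "culture": "c2", "value": 1.0},
    ])
    with pytest.raises(ValueError):
        two_way_anova(dup)


def test_two_way_drops_incomplete_culture():
    vals = dict(TOY)
    vals[("vehicle", "c3")] = 12.0  # c3 lacks the other groups
    res = two_way_anova(_tidy(vals))
    assert res.group_n.eq(2).all()


# ---------------------------------------------------------------------------
# Dunnett
# ---------------------------------------------------------------------------

def test_dunnett_k1_reduces_to_t_test():
    vals = {("vehicle", f"c{i}"): v for i, v in enumerate([1.0, 2.0, 3.0, 4.0])}
    vals.update({("1e-06", f"c{i}"): v for i, v in enumerate([2.0, 3.5, 4.0, 6.0])})
    df = _tidy(vals)
    res = two_way_anova(df)
    d = dunnett(df, "vehicle", anova=res)
    expected = 2 * sps.t.sf(abs(d["t"].iloc[0]), res.residual_df)
    assert d["p_adjusted"].iloc[0] == pytest.approx(expected, rel=1e-12)
    assert d["p_unadjusted"].iloc[0] == pytest.approx(expected, rel=1e-12)


def test_dunnett_zero_difference_p_one():
    vals = {(g, c): {"c1": 1.0, "c2": 2.0, "c3": 4.0}[c]
            for g in ("vehicle", "a", "b") for c in ("c1", "c2", "c3")}
    vals[("a", "c1")] += 0.3  # some residual variance
    vals[("a", "c3")] -= 0.3
    df = _tidy(vals)
    d = dunnett(df, "vehicle")
    b = d.set_index("group").loc["b"]
    assert b["t"] == pytest.approx(0.0)
    assert b["p_adjusted"] == pytest.approx(1.0)


def test_dunnett_adjusted_ge_unadjusted():
    rng = np.random.default_rng(21)
    for _ in range(5):
        vals = {(f"g{i}", f"c{j}"): float(rng.normal())
                for i in range(5) for j in range(4)}
        df = _tidy(vals)
        d = dunnett(df, "g0")
        assert (d["p_adjusted"] >= d["p_unadjusted"] - 1e-12).all()
        assert d["p_adjusted"].between(0, 1).all()


def test_dunnett_matches_scipy_one_way():
    """One-way balanced case: adjusted p agrees with the reference
    implementation to its own integration accuracy."""
    rng = np.random.default_rng(42)
    samples = {g: rng.normal(loc, 1.0, 6)
               for g, loc in zip(["ctrl", "a", "b", "c"], [0, 0.5, 1.0, -0.3])}
    df = pd.DataFrame([{"group": g, "value": v}
                       for g, vs in samples.items() for v in vs])
    res, mine = one_way_anova_dunnett(df, "ctrl")
    ref = sps.dunnett(samples["a"], samples["b"], samples["c"],
                      control=samples["ctrl"],
                      random_state=np.random.default_rng(0))
    mine = mine.set_index("group")
    for g, t_ref, p_ref in zip(["a", "b", "c"], ref.statistic, ref.pvalue):
        assert mine.loc[g, "t"] == pytest.approx(t_ref, rel=1e-9)
        assert mine.loc[g, "p_adjusted"] == pytest.approx(p_ref, abs=2e-3)


def test_dunnett_cdf_matches_monte_carlo():
    """Quadrature CDF agrees with a direct max-|T| simulation to 3 decimals."""
    k, df, rho = 5, 35, 0.5
    rng = np.random.default_rng(1)
    n = 400_000
    z0 = rng.standard_normal(n)
    zi = rng.standard_normal((n, k))
    z = np.sqrt(rho) * z0[:, None] + np.sqrt(1 - rho) * zi
    w = np.sqrt(rng.chisquare(df, n) / df)
    maxabs = np.abs(z).max(axis=1) / w
    for t in (1.5, 2.2, 2.8):
        mc = float((maxabs <= t).mean())
        assert dunnett_max_abs_t_cdf(t, k, df, rho) == pytest.approx(mc, abs=1.5e-3)


def test_dunnett_critical_value_inverts_cdf():
    crit = dunnett_critical_value(5, 35, alpha=0.05)
    assert dunnett_max_abs_t_cdf(crit, 5, 35) == pytest.approx(0.95, abs=1e-8)


def test_dunnett_unbalanced_mc_fallback():
    rng = np.random.default_rng(3)
    rows = []
    for g, n in [("ctrl", 8), ("a", 5), ("b", 7)]:
        for v in rng.normal(0.0, 1.0, n):
            rows.append({"group": g, "value": float(v)})
    df = pd.DataFrame(rows)
    res = one_way_anova(df)
    d = dunnett(df, "ctrl", anova=res, seed=7, mc_draws=200_000)
    ref = sps.dunnett(
        df[df["group"] == "a"]["value"], df[df["group"] == "b"]["value"],
        control=df[df["group"] == "ctrl"]["value"],
        random_state=np.random.default_rng(0))
    d = d.set_index("group")
    for g, p_ref in zip(["a", "b"], ref.pvalue):
        assert d.loc[g, "p_adjusted"] == pytest.approx(p_ref, abs=5e-3)


# ---------------------------------------------------------------------------
# one-way ANOVA
# ---------------------------------------------------------------------------

def test_one_way_two_groups_f_equals_t_squared():
    groups = {"a": [1.0, 2.0, 3.0, 4.0], "b": [2.5, 3.0, 4.5, 5.0]}
    df = pd.DataFrame([{"group": g, "value": v}
                       for g, vs in groups.items() for v in vs])
    res = one_way_anova(df)
    t = pooled_t(groups["a"], groups["b"])
    assert res.treatment_f == pytest.approx(t**2, rel=1e-9)


def test_one_way_matches_explicit_sums():
    groups = {"a": [35.0, 40.0, 30.0], "b": [60.0, 55.0, 65.0],
              "c": [50.0, 45.0, 52.0]}
    df = pd.DataFrame([{"group": g, "value": v}
                       for g, vs in groups.items() for v in vs])
    res = one_way_anova(df)
    oracle = anova_one_way_sums(groups)
    assert res.table.loc["treatment", "ss"] == pytest.approx(oracle["ss_treatment"])
    assert res.residual_df == oracle["df_residual"]
    assert res.treatment_f == pytest.approx(oracle["f_treatment"])


def test_one_way_constant_values_degenerate():
    df = pd.DataFrame([{"group": g, "value": 5.0}
                       for g in ("a", "a", "b", "b")])
    with pytest.raises(DegenerateDataError):
        one_way_anova(df)


# ---------------------------------------------------------------------------
# t-test
# ---------------------------------------------------------------------------

def test_t_test_identical_groups():
    res = t_test_unpaired([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert res.t == pytest.approx(0.0)
    assert res.p == pytest.approx(1.0)


def test_t_test_hand_formula_and_symmetry():
    x, y = [1.0, 2.0, 3.0], [2.0, 3.0, 4.0]
    res = t_test_unpaired(x, y)
    assert res.t == pytest.approx(pooled_t(x, y), rel=1e-12)
    assert res.df == 4
    swapped = t_test_unpaired(y, x)
    assert swapped.t == pytest.approx(-res.t)
    assert swapped.p == pytest.approx(res.p)
    with pytest.raises(DegenerateDataError):
        t_test_unpaired([1.0, 1.0], [1.0, 1.0])


# ---------------------------------------------------------------------------
# null calibration
# ---------------------------------------------------------------------------

def test_null_treatment_p_uniform():
    """Under the null, blocked-ANOVA treatment p-values pass a KS test for
    uniformity at the 1% level."""
    sim = simulate_null_anova(n_groups=6, n_cultures=8, n_reps=10_000, seed=5)
    ks = sps.kstest(sim["treatment_p"], "uniform")
    assert ks.pvalue > 0.01


def test_null_fwer_near_nominal():
    sim = simulate_null_anova(n_groups=6, n_cultures=8, n_reps=10_000, seed=5)
    crit = dunnett_critical_value(5, int(sim["residual_df"]), alpha=0.05)
    fwer = float((sim["max_abs_t"] > crit).mean())
    assert abs(fwer - 0.05) <= 0.01


def test_significance_stars():
    assert significance_stars(0.2) == ""
    assert significance_stars(0.03) == "*"
    assert significance_stars(0.004) == "**"
    assert significance_stars(0.0004) == "***"
    assert significance_stars(0.00004) == "****"
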