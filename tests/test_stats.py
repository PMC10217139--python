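import numpy as np
import pandas as pd
import pytest

from gliavasc.stats import (
    Design,
    anova_oneway,
    build_report,
    percent_change,
    shapiro_wilk,
    tukey_hsd,
    welch_t,
)


# ------------------------------------------------------------ Shapiro–Wilk

def test_shapiro_accepts_normal_samples_mostly():
    ok = 0
    for seed in range(100):
        x = np.random.default_rng(seed).normal(0, 1, 50)
        if shapiro_wilk(x).p_value > 0.05:
            ok += 1
    assert ok >= 90


def test_shapiro_rejects_bimodal():
    x = np.array([0.0] * 25 + [100.0] * 25) + np.linspace(0, 1e-6, 50)
    assert shapiro_wilk(x).p_value < 0.01


def test_shapiro_input_validation():
    with pytest.raises(ValueError):
        shapiro_wilk([1.0, 2.0])
    with pytest.raises(ValueError):
        shapiro_wilk([3.0, 3.0, 3.0])


# ------------------------------------------------------------------ ANOVA

def test_rm_anova_identical_per_subject_gives_f0_p1():
    groups = {"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0], "c": [1.0, 2.0, 3.0]}
    res = anova_oneway(groups, repeated=True)
    assert res.statistic == 0.0
    assert res.p_value == 1.0


def test_rm_anova_matches_pingouin():
    pg = pytest.importorskip("pingouin")
    rng = np.random.default_rng(3)
    n, k = 8, 3
    data = rng.normal(0, 1, (n, k)) + rng.normal(0, 1, (n, 1))
    data[:, 1] += 1.0
    groups = {f"c{j}": data[:, j] for j in range(k)}
    res = anova_oneway(groups, repeated=True)
    long = pd.DataFrame(
        {
            "y": data.ravel(),
            "cond": np.tile([f"c{j}" for j in range(k)], n),
            "subj": np.repeat(np.arange(n), k),
        }
    )
    ref = pg.rm_anova(data=long, dv="y", within="cond", subject="subj")
    assert res.statistic == pytest.approx(float(ref["F"][0]), rel=1e-6)
    assert res.p_value == pytest.approx(float(ref["p_unc"][0]), rel=1e-6)


def test_ordinary_anova_matches_statsmodels():
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    rng = np.random.default_rng(5)
    groups = {g: rng.normal(mu, 1, 7) for g, mu in [("a", 0), ("b", 0.5), ("c", 2)]}
    res = anova_oneway(groups)
    long = pd.DataFrame(
        {
            "y": np.concatenate(list(groups.values())),
            "g": np.repeat(list(groups), [len(v) for v in groups.values()]),
        }
    )
    tab = sm.stats.anova_lm(ols("y ~ C(g)", data=long).fit(), typ=1)
    assert res.statistic == pytest.approx(float(tab["F"].iloc[0]), rel=1e-6)
    assert res.p_value == pytest.approx(float(tab["PR(>F)"].iloc[0]), rel=1e-6)


def test_two_group_anova_equals_pooled_t_squared():
    rng = np.random.default_rng(9)
    a, b = rng.normal(0, 1, 10), rng.normal(0.8, 1, 10)
    from scipy import stats as sps

    t = sps.ttest_ind(a, b, equal_var=True).statistic
    res = anova_oneway({"a": a, "b": b})
    assert res.statistic == pytest.approx(t**2, rel=1e-10)


def test_anova_input_validation():
    with pytest.raises(ValueError):
        anova_oneway({"a": [1, 2, 3]})
    with pytest.raises(ValueError):
        anova_oneway({"a": [1, 2, 3], "b": [1, 2]}, repeated=True)


# ------------------------------------------------------------------ Tukey

def test_tukey_identical_groups_p_near_one():
    res = tukey_hsd({"a": [1.0, 2, 3, 4], "b": [1.0, 2, 3, 4]})
    assert res[0].p_value > 0.99


def test_tukey_matches_statsmodels():
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    rng = np.random.default_rng(7)
    groups = {g: rng.normal(mu, 1, 8) for g, mu in [("a", 0), ("b", 1), ("c", 3)]}
    ours = {r.comparison: r.p_value for r in tukey_hsd(groups)}
    ref = pairwise_tukeyhsd(
        np.concatenate(list(groups.values())),
        np.repeat(list(groups), [8, 8, 8]),
    )
    for (g1, g2, p) in zip(
        ref.groupsunique[np.array(ref._multicomp.pairindices[0])],
        ref.groupsunique[np.array(ref._multicomp.pairindices[1])],
        ref.pvalues,
    ):
        key = f"{g1} vs {g2}"
        assert ours[key] == pytest.approx(p, abs=1e-6)


def test_tukey_outlier_group_has_smallest_ps():
    rng = np.random.default_rng(11)
    groups = {
        "a": rng.normal(0, 1, 6),
        "b": rng.normal(0.2, 1, 6),
        "far": rng.normal(10, 1, 6),
    }
    res = tukey_hsd(groups)
    ps = {r.comparison: r.p_value for r in res}
    assert max(ps["a vs far"], ps["b vs far"]) < ps["a vs b"]


def test_tukey_adjusted_p_not_below_unadjusted(rng):
    # the studentized-range family p can only exceed the per-contrast p
    # computed from the same pooled error term
    from scipy import stats as sps

    for _ in range(20):
        groups = {
            g: rng.normal(rng.uniform(0, 2), 1, 6) for g in ("a", "b", "c")
        }
        arrays = list(groups.values())
        df_err = sum(len(a) - 1 for a in arrays)
        mse = sum((len(a) - 1) * a.var(ddof=1) for a in arrays) / df_err
        adj = {r.comparison: r.p_value for r in tukey_hsd(groups)}
        for g1, g2 in (("a", "b"), ("a", "c"), ("b", "c")):
            a, b = groups[g1], groups[g2]
            t = (a.mean() - b.mean()) / np.sqrt(mse * (1 / len(a) + 1 / len(b)))
            raw = 2 * sps.t.sf(abs(t), df_err)
            assert adj[f"{g1} vs {g2}"] >= raw - 1e-9


# ---------------------------------------------------------------- Welch t

def test_welch_identical_samples():
    res = welch_t([1.0, 2, 3], [1.0, 2, 3])
    assert res.statistic == 0.0
    assert res.p_value == pytest.approx(1.0)


def test_welch_matches_closed_form():
    a = np.array([1.0, 2.0, 4.0, 3.0, 5.0])
    b = np.array([2.5, 4.5, 6.0, 5.5])
    res = welch_t(a, b)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    assert res.statistic == pytest.approx(t, rel=1e-12)
    assert res.df[0] == pytest.approx(df, rel=1e-12)


def test_welch_equals_pooled_t_for_equal_n_equal_variance(rng):
    from scipy import stats as sps

    a = rng.normal(0, 1, 12)
    b = rng.normal(1, 1, 12)
    w = welch_t(a, b)
    p = sps.ttest_ind(a, b, equal_var=True)
    assert w.statistic == pytest.approx(p.statistic, abs=1e-10)


def test_welch_input_validation():
    with pytest.raises(ValueError):
        welch_t([1.0], [1.0, 2.0])


# ---------------------------------------------------------- percent change

@pytest.mark.parametrize(
    "baseline,value,expected",
    [(226.9, 334.9, 47.6), (704.8, 1089.0, 54.5), (1089.0, 842.8, -22.6),
     (13.2, 6.06, -54.1), (5.0, 5.0, 0.0)],
)
def test_percent_change_worked_examples(baseline, value, expected):
    assert percent_change(baseline, value) == expected


def test_percent_change_antisymmetry_identity(rng):
    # forward and reverse changes are tied by pc(a,b) = -pc(b,a)·b/a
    for _ in range(50):
        a, b = rng.uniform(1, 1000, 2)
        fwd = 100 * (b - a) / a
        rev = 100 * (a - b) / b
        assert fwd == pytest.approx(-rev * b / a, rel=1e-9)
        assert percent_change(a, b) == pytest.approx(fwd, abs=0.05001)
    with pytest.raises(ValueError):
        percent_change(0.0, 5.0)


# ------------------------------------------------------------ build_report

def _measurements(shift=2.0, n=5, rng=None):
    rng = rng or np.random.default_rng(0)
    rows = []
    for cond, mu in (("control", 10.0), ("lps", 10.0 + shift)):
        for s in range(n):
            for rep in range(3):
                rows.append(
                    {"condition": cond, "subject": f"m{s}",
                     "value": rng.normal(mu, 0.5)}
                )
    return pd.DataFrame(rows)


def test_report_recovers_known_shift():
    df = _measurements(shift=2.0)
    design = Design(("control", "lps"), "control", paired=True)
    rep = build_report(df, design)
    s = rep["summary"].set_index("condition")
    diff = s.loc["lps", "mean"] - s.loc["control", "mean"]
    se = np.sqrt(s.loc["lps", "sd"] ** 2 / 5 + s.loc["control", "sd"] ** 2 / 5)
    assert abs(diff - 2.0) < 3 * se
    assert rep["omnibus"].p_value < 0.05
    assert rep["pairwise"][0].test == "tukey_hsd"


def test_report_single_condition_warns_and_skips_tests():
    df = _measurements()
    df = df[df["condition"] == "control"]
    rep = build_report(df, Design(("control",), "control"))
    assert rep["omnibus"] is None
    assert "warning" in rep


def test_report_paired_subject_mismatch_raises():
    df = _measurements()
    df.loc[df["condition"] == "lps", "subject"] = "other"
    with pytest.raises(ValueError):
        build_report(df, Design(("control", "lps"), "control", paired=True))


def test_report_missing_condition_raises():
    df = _measurements()
    with pytest.raises(ValueError):
        build_report(df, Design(("control", "lps", "day8"), "control"))
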