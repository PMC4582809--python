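"""Scoring, summaries, mixed ANOVA, t tests, ANCOVA and Fisher-z
correlations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from confusel import (
    accuracy_covariate_correlations,
    accuracy_summary,
    fisher_z,
    itemwise_ancova_interaction,
    mixed_anova,
    score_naming,
    t_test,
)


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def test_score_naming_rules():
    targets = {
        "apple": {"name": "apple", "synonyms": []},
        "mug": {"name": "mug", "synonyms": ["cup"]},
        "wolf": {"name": "wolf", "synonyms": []},
    }
    responses = pd.DataFrame(
        {
            "participant": ["p1"] * 4,
            "item": ["apple", "mug", "wolf", "apple"],
            "response": ["Apple", "cup", "dog", None],
        }
    )
    out = score_naming(responses, targets)
    assert out["correct"].tolist() == [1, 1, 0, 0]  # case fold, synonym, wrong, missing
    with pytest.raises(ValueError, match="unknown items"):
        score_naming(
            pd.DataFrame({"participant": ["p"], "item": ["dragon"], "response": ["x"]}),
            targets,
        )


def test_accuracy_summary_participant_then_cell():
    acc = pd.DataFrame(
        {
            "participant": ["a"] * 10 + ["b"] * 10,
            "group": ["g"] * 20,
            "item": list(range(10)) * 2,
            "correct": [1] * 5 + [0] * 5 + [1] * 7 + [0] * 3,
        }
    )
    out = accuracy_summary(acc, by=["group"])
    assert out.loc[0, "mean_pct"] == pytest.approx(60.0)  # mean of 50% and 70%
    assert out.loc[0, "sem_pct"] == pytest.approx(10.0)
    single = accuracy_summary(acc[acc.participant == "a"].assign(correct=1), by=["group"])
    assert single.loc[0, "mean_pct"] == 100.0
    assert single.loc[0, "sem_pct"] == 0.0


# ---------------------------------------------------------------------------
# mixed ANOVA
# ---------------------------------------------------------------------------

def _mixed_dataset(seed=0, sizes=(8, 6, 15), within_levels=("w1", "w2"), offsets=(0.0, 0.5)):
    rng = np.random.default_rng(seed)
    rows = []
    for g, n in zip("ABC", sizes):
        for s in range(n):
            base = rng.normal()
            for w, off in zip(within_levels, offsets):
                rows.append(
                    dict(participant=f"{g}{s}", group=g, cond=w,
                         y=base + off + rng.normal())
                )
    return pd.DataFrame(rows)


def test_mixed_anova_type3_oracle():
    """Frozen oracle: car::Anova(type=3) univariate repeated-measures output
    for this exact dataset (unequal groups, one within factor)."""
    df = _mixed_dataset(seed=0)
    res = {r.effect: r for r in mixed_anova(df, dv="y", within=["cond"])}
    assert res["group"].statistic == pytest.approx(0.2780, abs=2e-4)
    assert res["group"].p == pytest.approx(0.759498, abs=1e-5)
    assert res["cond"].statistic == pytest.approx(10.3988, abs=2e-4)
    assert res["cond"].p == pytest.approx(0.003388, abs=1e-5)
    assert res["group:cond"].statistic == pytest.approx(0.4943, abs=2e-4)
    assert res["group"].df == (2.0, 26.0)
    assert res["cond"].df == (1.0, 26.0)


def test_mixed_anova_matches_pingouin_equal_n():
    pg = pytest.importorskip("pingouin")
    df = _mixed_dataset(seed=4, sizes=(7, 7, 7))
    mine = {r.effect: r for r in mixed_anova(df, dv="y", within=["cond"])}
    ref = pg.mixed_anova(data=df, dv="y", within="cond",
                        subject="participant", between="group").set_index("Source")
    assert mine["group"].statistic == pytest.approx(ref.loc["group", "F"])
    assert mine["cond"].statistic == pytest.approx(ref.loc["cond", "F"])
    assert mine["group:cond"].statistic == pytest.approx(ref.loc["Interaction", "F"])


def test_mixed_anova_reduces_to_one_way():
    """With a single within level the only test is the classical one-way
    ANOVA on participant means."""
    df = _mixed_dataset(seed=2, within_levels=("only",), offsets=(0.0,))
    res = mixed_anova(df, dv="y", within=["cond"])
    assert len(res) == 1
    means = df.groupby(["participant", "group"])["y"].mean().reset_index()
    f_ref, p_ref = stats.f_oneway(
        *[means.loc[means.group == g, "y"] for g in "ABC"]
    )
    assert res[0].statistic == pytest.approx(f_ref)
    assert res[0].p == pytest.approx(p_ref)


def test_mixed_anova_group_offset_only():
    """Data with a pure group offset and no within variation: group F equals
    the closed-form one-way ANOVA on participant means; within and
    interaction F are 0."""
    rows = []
    rng = np.random.default_rng(6)
    for g, off in zip("AB", (0.0, 1.0)):
        for s in range(4):
            base = off + rng.normal() * 0.3
            for w in ("w1", "w2"):
                rows.append(dict(participant=f"{g}{s}", group=g, cond=w, y=base))
    df = pd.DataFrame(rows)
    res = {r.effect: r for r in mixed_anova(df, dv="y", within=["cond"])}
    means = df.groupby(["participant", "group"])["y"].mean().reset_index()
    f_ref, _ = stats.f_oneway(*[means.loc[means.group == g, "y"] for g in "AB"])
    assert res["group"].statistic == pytest.approx(f_ref)
    assert res["cond"].statistic == 0.0
    assert res["group:cond"].statistic == 0.0


def test_mixed_anova_two_within_factors_structure():
    rng = np.random.default_rng(7)
    rows = []
    for g, n in zip("AB", (5, 6)):
        for s in range(n):
            base = rng.normal()
            for dmn in ("living", "nonliving"):
                for dist in ("close", "distant"):
                    y = base + (0.4 if dist == "distant" else 0) + rng.normal() * 0.5
                    rows.append(dict(participant=f"{g}{s}", group=g,
                                     domain=dmn, distance=dist, y=y))
    df = pd.DataFrame(rows)
    res = {r.effect: r for r in mixed_anova(df, dv="y", within=["domain", "distance"])}
    expected = {
        "group", "domain", "distance", "domain:distance",
        "group:domain", "group:distance", "group:domain:distance",
    }
    assert set(res) == expected
    assert res["distance"].p < 0.01  # the injected effect
    assert res["group"].df == (1.0, 9.0)
    assert res["domain"].df == (1.0, 9.0)


def test_mixed_anova_degenerate_constant():
    df = _mixed_dataset(seed=3)
    df["y"] = 1.0
    res = mixed_anova(df, dv="y", within=["cond"])
    for r in res:
        assert r.statistic == 0.0
        assert any("degenerate" in f for f in r.flags)


def test_mixed_anova_errors():
    df = _mixed_dataset(seed=5)
    with pytest.raises(ValueError, match="missing within cells"):
        mixed_anova(df.iloc[1:], dv="y", within=["cond"])
    tiny = df[df.participant.isin(["A0", "B0", "B1"])]
    with pytest.raises(ValueError, match="fewer than two"):
        mixed_anova(tiny, dv="y", within=["cond"])


# ---------------------------------------------------------------------------
# t tests
# ---------------------------------------------------------------------------

def test_t_test_against_scipy():
    rng = np.random.default_rng(10)
    x, y = rng.normal(0, 1, 10), rng.normal(0.5, 2, 12)
    pooled = t_test(x, y)
    ref = stats.ttest_ind(x, y)
    assert pooled.statistic == pytest.approx(ref.statistic)
    assert pooled.p == pytest.approx(ref.pvalue)
    welch = t_test(x, y, welch=True)
    refw = stats.ttest_ind(x, y, equal_var=False)
    assert welch.statistic == pytest.approx(refw.statistic)
    assert welch.df == pytest.approx(refw.df)
    paired = t_test(x, y[:10], paired=True)
    refp = stats.ttest_rel(x, y[:10])
    assert paired.statistic == pytest.approx(refp.statistic)
    assert paired.p == pytest.approx(refp.pvalue)


def test_welch_equals_pooled_at_equal_variance_and_n():
    rng = np.random.default_rng(14)
    x = rng.normal(size=9)
    y = x[::-1] + 0.3  # identical sample variance, equal n
    pooled, welch = t_test(x, y), t_test(x, y, welch=True)
    assert welch.statistic == pytest.approx(pooled.statistic)
    assert welch.df == pytest.approx(pooled.df)


def test_one_tailed_convention():
    rng = np.random.default_rng(15)
    x = rng.normal(1.0, 1, 20)
    y = rng.normal(0.0, 1, 20)
    two = t_test(x, y, tail="two")
    one = t_test(x, y, tail="one", direction="greater")
    assert one.p == pytest.approx(two.p / 2)  # effect in hypothesised direction
    against = t_test(x, y, tail="one", direction="less")
    assert against.p == pytest.approx(1 - two.p / 2)
    assert "opposite" in against.flags[0]


def test_t_test_zero_variance_paths():
    res = t_test([1.0, 1.0, 1.0], [1.0, 1.0], tail="two")
    assert res.statistic == 0.0 and res.p == 1.0 and res.flags
    with pytest.raises(ValueError, match="zero variance"):
        t_test([1.0, 1.0], [2.0, 2.0])
    x = np.array([1.0, 2.0, 3.0])
    same = t_test(x, x, paired=True)
    assert same.statistic == 0.0 and same.p == 1.0 and same.flags
    with pytest.raises(ValueError, match="nonzero mean"):
        t_test(x + 1, x, paired=True)


# ---------------------------------------------------------------------------
# item-wise ANCOVA
# ---------------------------------------------------------------------------

def _ancova_data(slopes, n_items=40, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    cov = rng.normal(size=n_items)
    rows = []
    for g, (icpt, slope) in slopes.items():
        acc = icpt + slope * cov + rng.normal(0, noise, n_items)
        for i in range(n_items):
            rows.append(dict(item=f"i{i}", group=g, accuracy=acc[i], cov=cov[i]))
    return pd.DataFrame(rows)


def test_ancova_identical_slopes_no_interaction():
    """Residuals constructed orthogonal to the interaction regressor: the
    group x covariate term explains exactly nothing, F = 0, p = 1."""
    df = _ancova_data({"A": (0.5, 0.3), "B": (0.7, 0.3), "C": (0.6, 0.3)})
    rng = np.random.default_rng(1)
    g1 = (df["group"] == "B").to_numpy(float)
    g2 = (df["group"] == "C").to_numpy(float)
    c = df["cov"].to_numpy()
    X = np.column_stack([np.ones_like(c), g1, g2, c, g1 * c, g2 * c])
    e = rng.normal(size=len(df))
    e = e - X @ np.linalg.lstsq(X, e, rcond=None)[0]  # project off the full model
    df["accuracy"] = df["accuracy"] + e
    res = itemwise_ancova_interaction(df, covariate="cov")
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.p == pytest.approx(1.0)


def test_ancova_matches_normal_equations_oracle():
    """Interaction F from a brute-force nested-model fit on a 10-item table."""
    df = _ancova_data({"A": (0.5, 0.1), "B": (0.8, -0.4)}, n_items=10, noise=0.2, seed=3)
    res = itemwise_ancova_interaction(df, covariate="cov")

    g = (df["group"] == "B").to_numpy(float)
    c = df["cov"].to_numpy()
    y = df["accuracy"].to_numpy()
    X_full = np.column_stack([np.ones_like(c), g, c, g * c])
    X_red = X_full[:, :3]

    def rss(X):
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        r = y - X @ beta
        return float(r @ r)

    rss_f, rss_r = rss(X_full), rss(X_red)
    df2 = len(y) - X_full.shape[1]
    f_ref = (rss_r - rss_f) / 1 / (rss_f / df2)
    assert res.statistic == pytest.approx(f_ref, rel=1e-8)
    assert res.df == (1.0, float(df2))


def test_ancova_detects_slope_difference():
    """With a large injected slope difference across groups the interaction
    is significant in >= 95% of simulated item sets (200 runs, 200 items)."""
    hits = 0
    for i in range(200):
        df = _ancova_data(
            {"A": (0.6, 0.02), "B": (0.6, 0.10), "C": (0.6, 0.02)},
            n_items=200, noise=0.15, seed=1000 + i,
        )
        hits += itemwise_ancova_interaction(df, covariate="cov").p < 0.05
    assert hits / 200 >= 0.95


def test_ancova_constant_covariate_error():
    df = _ancova_data({"A": (0.5, 0.0), "B": (0.5, 0.0)})
    df["cov"] = 1.0
    with pytest.raises(ValueError, match="constant"):
        itemwise_ancova_interaction(df, covariate="cov")


# ---------------------------------------------------------------------------
# covariate correlations and the Fisher transform
# ---------------------------------------------------------------------------

def test_fisher_transform_properties():
    assert fisher_z(0.0) == 0.0
    assert fisher_z(0.5) == pytest.approx(0.5493, abs=1e-4)
    z = np.linspace(-5, 5, 41)
    assert np.allclose(np.arctanh(np.tanh(z)), z, atol=1e-12)
    r = np.linspace(-0.99, 0.99, 21)
    assert np.all(np.diff(fisher_z(r)) > 0)  # strictly increasing
    assert np.allclose(fisher_z(-r), -fisher_z(r))  # odd


def test_participant_level_correlations():
    rng = np.random.default_rng(20)
    items = [f"i{k}" for k in range(40)]
    cov = pd.DataFrame({"s": rng.normal(size=40)}, index=pd.Index(items, name="item"))
    # participant whose accuracy tracks the covariate deterministically
    acc = pd.DataFrame(
        {
            "participant": ["det"] * 40 + ["rand"] * 40,
            "group": ["g1"] * 80,
            "item": items * 2,
            "correct": np.concatenate(
                [(cov["s"] > 0).astype(int).to_numpy(),
                 rng.integers(0, 2, size=40)]
            ),
        }
    )
    out = accuracy_covariate_correlations(acc, cov).set_index("participant")
    r_det = out.loc["det", "r"]
    ref, _ = stats.pearsonr(acc.loc[acc.participant == "det", "correct"], cov["s"])
    assert r_det == pytest.approx(ref)
    assert out.loc["det", "z"] == pytest.approx(np.arctanh(r_det))

    # covariate identical to accuracy -> r = 1, z = inf, flagged
    cov2 = pd.DataFrame(
        {"s": acc.loc[acc.participant == "det", "correct"].to_numpy(float)},
        index=pd.Index(items, name="item"),
    )
    out2 = accuracy_covariate_correlations(
        acc[acc.participant == "det"], cov2
    ).set_index("participant")
    assert np.isinf(out2.loc["det", "z"])
    assert bool(out2.loc["det", "degenerate"])


def test_group_level_correlations_include_differences():
    rng = np.random.default_rng(22)
    items = [f"i{k}" for k in range(30)]
    cov = pd.DataFrame({"s": rng.normal(size=30)}, index=pd.Index(items, name="item"))
    rows = []
    for g in ("ctrl", "dmg"):
        for p in range(3):
            for it in items:
                rows.append(dict(participant=f"{g}{p}", group=g, item=it,
                                 correct=int(rng.random() < 0.8)))
    acc = pd.DataFrame(rows)
    out = accuracy_covariate_correlations(acc, cov, level="group")
    assert set(out["contrast"]) == {"ctrl", "dmg", "ctrl-dmg"}
    item_means = acc.groupby(["group", "item"])["correct"].mean().unstack("group")
    diff = (item_means["ctrl"] - item_means["dmg"]).reindex(cov.index)
    ref, _ = stats.pearsonr(diff, cov["s"])
    got = out.set_index(["contrast", "covariate"]).loc[("ctrl-dmg", "s"), "r"]
    assert got == pytest.approx(ref)
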