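"""Scoring and statistical analysis of naming / word-picture accuracy.

Covers the statistics a patient-group accuracy study needs:

* :func:`score_naming` — mark spoken responses correct against canonical
  names and synonyms;
* :func:`accuracy_summary` — group x condition mean percent correct with
  between-participant SEM (participant means first, then the cell mean);
* :func:`mixed_anova` — mixed-design ANOVA with one between-subjects
  factor (group) and up to two within-subjects factors, using the
  participant as the error stratum for within effects.  Implemented via
  orthonormal within-cell contrast variables, the classical univariate
  approach, so it handles unequal group sizes (Type-III-style unweighted
  means for purely-within effects);
* :func:`t_test` — pooled, Welch and paired t tests with explicit tails;
* :func:`itemwise_ancova_interaction` — group x covariate interaction in
  an item-wise ANCOVA (items as observations);
* :func:`accuracy_covariate_correlations` — item-wise accuracy-covariate
  Pearson correlations per group or per participant, the latter Fisher
  transformed (z = atanh r) for use as per-patient effect scores.

Accuracy tables are plain DataFrames with one row per participant x item
(or participant x condition cell), columns ``participant, group, item,
correct`` plus joinable item metadata.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("confusel")

__all__ = [
    "TestResult",
    "results_table",
    "score_naming",
    "accuracy_summary",
    "mixed_anova",
    "t_test",
    "itemwise_ancova_interaction",
    "accuracy_covariate_correlations",
    "fisher_z",
]


@dataclass
class TestResult:
    """One inferential statistic: F, t, r or rho with df, p and tail."""

    statistic: float
    df: float | tuple[float, float]
    p: float
    kind: str  # F | t | r | rho
    tail: str = "two"  # one | two
    effect: str = ""
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0 or np.isnan(self.p)):
            raise ValueError(f"p out of range: {self.p}")

    @property
    def df1(self) -> float:
        return self.df[0] if isinstance(self.df, tuple) else self.df

    @property
    def df2(self) -> float:
        return self.df[1] if isinstance(self.df, tuple) else np.nan


def results_table(results: Sequence[TestResult]) -> pd.DataFrame:
    """Stable-schema table of test results (for TSV reports)."""
    return pd.DataFrame(
        {
            "effect": [r.effect for r in results],
            "kind": [r.kind for r in results],
            "statistic": [r.statistic for r in results],
            "df1": [r.df1 for r in results],
            "df2": [r.df2 for r in results],
            "p": [r.p for r in results],
            "tail": [r.tail for r in results],
            "flags": [";".join(r.flags) for r in results],
        }
    )


def fisher_z(r: float | np.ndarray) -> float | np.ndarray:
    """Fisher r-to-z transformation, z = atanh(r)."""
    return np.arctanh(r)


# ---------------------------------------------------------------------------
# scoring and summaries
# ---------------------------------------------------------------------------

def _fold(s: str) -> str:
    return str(s).strip().casefold()


def score_naming(
    responses: pd.DataFrame,
    targets: Mapping[str, Mapping[str, object]],
) -> pd.DataFrame:
    """Score spoken naming responses against canonical names and synonyms.

    ``targets`` maps item id -> ``{"name": canonical, "synonyms": [...]}``.
    A response is correct iff, case-folded and trimmed, it equals the
    canonical name or any synonym.  Missing responses score 0 (logged);
    responses for unknown items are an error.
    """
    required = {"participant", "item", "response"}
    missing = required - set(responses.columns)
    if missing:
        raise ValueError(f"responses missing columns: {sorted(missing)}")
    unknown = set(responses["item"]) - set(targets)
    if unknown:
        raise ValueError(f"responses for unknown items: {sorted(unknown)}")

    accepted = {
        item: {_fold(spec["name"])} | {_fold(s) for s in spec.get("synonyms", ())}
        for item, spec in targets.items()
    }
    out = responses.copy()
    is_missing = out["response"].isna() | (out["response"].astype(str).str.strip() == "")
    n_missing = int(is_missing.sum())
    if n_missing:
        logger.info("score_naming: %d missing responses scored incorrect", n_missing)
    out["correct"] = [
        0 if miss else int(_fold(resp) in accepted[item])
        for miss, resp, item in zip(is_missing, out["response"], out["item"])
    ]
    return out.drop(columns="response")


def accuracy_summary(
    acc: pd.DataFrame,
    by: Sequence[str],
    value: str = "correct",
    participant: str = "participant",
) -> pd.DataFrame:
    """Mean percent correct and between-participant SEM per cell of ``by``.

    Participant means are computed first within each cell, then averaged
    across participants; the SEM is over participants.  Cells with no data
    are flagged.  ``value`` may be trial-level 0/1 or a participant-level
    proportion in [0, 1].
    """
    by = list(by)
    for col in by:
        if col not in acc.columns:
            raise KeyError(f"unknown factor: {col!r}")
    per_part = acc.groupby([participant] + by, observed=True)[value].mean().reset_index()
    g = per_part.groupby(by, observed=True)[value]
    summary = g.agg(
        mean_pct=lambda s: 100.0 * s.mean(),
        sem_pct=lambda s: 100.0 * s.std(ddof=1) / np.sqrt(len(s)) if len(s) > 1 else 0.0,
        n="count",
    ).reset_index()
    summary["empty"] = summary["n"] == 0
    return summary


# ---------------------------------------------------------------------------
# mixed-design ANOVA
# ---------------------------------------------------------------------------

def _orthonormal_contrasts(levels: int) -> np.ndarray:
    """(levels-1, levels) orthonormal rows spanning the space orthogonal to
    the constant vector."""
    centering = np.eye(levels) - 1.0 / levels
    u, s, _ = np.linalg.svd(centering)
    return u[:, : levels - 1].T


def _gg_epsilon(cov: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the covariance of the orthonormal
    contrast variables (Box's epsilon on the sphericity-transformed scale)."""
    k = cov.shape[0]
    tr = np.trace(cov)
    denom = k * np.trace(cov @ cov)
    return float(tr**2 / denom) if denom > 0 else 1.0


def mixed_anova(
    data: pd.DataFrame,
    dv: str,
    subject: str = "participant",
    between: str = "group",
    within: Sequence[str] = (),
    gg_correction: bool = False,
) -> list[TestResult]:
    """Mixed-design ANOVA on participant-level cell means.

    One between-subjects factor and at most two fully-crossed
    within-subjects factors; every participant must contribute exactly one
    value per within cell (balanced within-design), groups may differ in
    size.  Returns F tests (two-tailed by construction) for the group main
    effect, every within effect and every within x group interaction, with
    the participant as the error stratum: subjects-within-groups for the
    group effect, effect x subjects-within-groups for each within effect.

    With ``gg_correction`` the Greenhouse-Geisser epsilon scales the df of
    within effects (off by default).
    """
    within = list(within)
    if len(within) > 2:
        raise ValueError("at most two within-subjects factors are supported")
    cols = [subject, between, dv] + within
    for c in cols:
        if c not in data.columns:
            raise KeyError(f"column missing from data: {c!r}")

    groups_per_subject = data.groupby(subject, observed=True)[between].nunique()
    if (groups_per_subject > 1).any():
        bad = list(groups_per_subject[groups_per_subject > 1].index)
        raise ValueError(f"subjects appear in more than one group: {bad}")
    subj_group = data.groupby(subject, observed=True)[between].first()
    group_levels = sorted(subj_group.unique())
    if len(group_levels) < 2:
        raise ValueError("need at least two groups")
    sizes = subj_group.value_counts()
    if (sizes < 2).any():
        bad = list(sizes[sizes < 2].index)
        raise ValueError(f"groups with fewer than two participants: {bad}")

    levels = {f: sorted(data[f].unique()) for f in within}
    if within:
        pivot = data.pivot_table(
            index=subject, columns=within, values=dv, aggfunc="mean", observed=True
        )
        pivot = pivot.reindex(
            columns=pd.MultiIndex.from_product([levels[f] for f in within], names=within)
            if len(within) > 1
            else pd.Index(levels[within[0]], name=within[0])
        )
        if pivot.isna().any().any():
            missing = [
                (s, c) for s in pivot.index for c in pivot.columns if pd.isna(pivot.loc[s, c])
            ]
            raise ValueError(f"missing within cells: {missing[:20]}")
        counts = data.groupby([subject] + within, observed=True)[dv].count()
        if (counts != 1).any():
            logger.info("mixed_anova: cells with multiple observations were averaged")
        Y = pivot.to_numpy(float)
        subjects = list(pivot.index)
    else:
        ymeans = data.groupby(subject, observed=True)[dv].mean()
        Y = ymeans.to_numpy(float)[:, None]
        subjects = list(ymeans.index)

    g_of = subj_group.reindex(subjects).to_numpy()
    group_masks = [g_of == g for g in group_levels]
    n_g = np.array([m.sum() for m in group_masks], dtype=float)
    G, N = len(group_levels), len(subjects)

    contrast = {f: _orthonormal_contrasts(len(levels[f])) for f in within}
    meanvec = {f: np.ones((1, len(levels[f]))) / np.sqrt(len(levels[f])) for f in within}

    results: list[TestResult] = []

    def _f_result(effect, ss_eff, df_eff, ss_err, df_err, flags=()):
        flags = list(flags)
        if ss_err <= 1e-12 * max(1.0, abs(ss_eff)):
            if ss_eff <= 1e-12:
                F, p = 0.0, 1.0
            else:
                F, p = np.inf, 0.0
            flags.append("degenerate: zero residual variance")
        else:
            F = (ss_eff / df_eff) / (ss_err / df_err)
            p = float(stats.f.sf(F, df_eff, df_err))
        results.append(
            TestResult(
                statistic=float(F), df=(float(df_eff), float(df_err)), p=float(p),
                kind="F", tail="two", effect=effect, flags=flags,
            )
        )

    # --- between stratum: group effect on the subject-mean contrast variable
    z0 = Y.sum(axis=1) / np.sqrt(Y.shape[1])
    gmeans = np.array([z0[m].mean() for m in group_masks])
    grand_w = float(n_g @ gmeans / N)
    ss_group = float(n_g @ (gmeans - grand_w) ** 2)
    ss_err_b = float(sum(((z0[m] - gm) ** 2).sum() for m, gm in zip(group_masks, gmeans)))
    _f_result(between, ss_group, G - 1, ss_err_b, N - G)

    # --- within strata: one per non-empty subset of within factors
    for size in range(1, len(within) + 1):
        for combo in itertools.combinations(within, size):
            mats = [contrast[f] if f in combo else meanvec[f] for f in within]
            C = mats[0]
            for m in mats[1:]:
                C = np.kron(C, m)
            k = C.shape[0]  # df of the effect
            if k == 0:  # a within factor with a single level contributes nothing
                continue
            Z = Y @ C.T  # (N, k) contrast variables
            zg = np.stack([Z[m].mean(axis=0) for m in group_masks])  # (G, k)
            zu = zg.mean(axis=0)  # unweighted grand means
            zw = n_g @ zg / N  # weighted grand means
            ss_eff = float((G**2 / (1.0 / n_g).sum()) * (zu**2).sum())
            ss_int = float(sum(n_g[g] * ((zg[g] - zw) ** 2).sum() for g in range(G)))
            resid = Z - zg[np.searchsorted(group_levels, g_of)]
            ss_err = float((resid**2).sum())
            df_err = (N - G) * k
            eps, flags = 1.0, []
            if gg_correction and k > 1:
                pooled = resid.T @ resid / (N - G)
                eps = _gg_epsilon(pooled)
                flags = [f"greenhouse-geisser epsilon={eps:.4f}"]
            name = ":".join(combo)
            _f_result(name, ss_eff, k * eps, ss_err, df_err * eps, flags)
            _f_result(f"{between}:{name}", ss_int, (G - 1) * k * eps, ss_err, df_err * eps, flags)

    return results


# ---------------------------------------------------------------------------
# t tests
# ---------------------------------------------------------------------------

def t_test(
    x,
    y,
    paired: bool = False,
    welch: bool = False,
    tail: str = "two",
    direction: str = "greater",
) -> TestResult:
    """Two-sample (pooled or Welch-Satterthwaite) or paired t test.

    ``tail='one'`` halves the two-tailed p in the hypothesised
    ``direction`` ('greater': mean(x) > mean(y)); against the hypothesis
    the one-tailed p is its complement.  Zero variance in both samples
    with equal means returns t = 0, p = 1, flagged; zero variance with
    unequal means is an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if tail not in ("one", "two"):
        raise ValueError("tail must be 'one' or 'two'")
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    flags: list[str] = []

    if paired:
        if len(x) != len(y):
            raise ValueError("paired test requires equal-length samples")
        if len(x) < 2:
            raise ValueError("need at least two pairs")
        d = x - y
        if np.ptp(d) == 0:
            if d[0] == 0:
                return TestResult(0.0, float(len(d) - 1), 1.0, "t", tail,
                                  "paired", ["zero-variance differences"])
            raise ValueError("zero variance in differences with nonzero mean")
        t, df = float(np.mean(d) / (np.std(d, ddof=1) / np.sqrt(len(d)))), len(d) - 1
        effect = "paired"
    else:
        if len(x) < 2 or len(y) < 2:
            raise ValueError("need at least two values per sample")
        vx, vy = np.var(x, ddof=1), np.var(y, ddof=1)
        if vx == 0 and vy == 0:
            if np.mean(x) == np.mean(y):
                df = len(x) + len(y) - 2
                return TestResult(0.0, float(df), 1.0, "t", tail,
                                  "two-sample", ["zero variance in both samples"])
            raise ValueError("zero variance in both samples with unequal means")
        res = stats.ttest_ind(x, y, equal_var=not welch)
        t = float(res.statistic)
        df = float(res.df)
        effect = "welch" if welch else "two-sample"

    p_two = 2.0 * stats.t.sf(abs(t), df)
    if tail == "two":
        p = p_two
    else:
        p = stats.t.sf(t, df) if direction == "greater" else stats.t.cdf(t, df)
        wrong_way = (direction == "greater" and t < 0) or (direction == "less" and t > 0)
        if wrong_way:
            flags.append("effect opposite to hypothesised direction")
    return TestResult(float(t), float(df), float(min(p, 1.0)), "t", tail, effect, flags)


# ---------------------------------------------------------------------------
# item-wise ANCOVA and covariate correlations
# ---------------------------------------------------------------------------

def itemwise_ancova_interaction(
    item_acc: pd.DataFrame,
    covariate: str | pd.Series,
    dv: str = "accuracy",
    group: str = "group",
    item: str = "item",
) -> TestResult:
    """Group x covariate interaction from an item-wise ANCOVA.

    ``item_acc`` is long-format with one row per item x group carrying the
    group's mean accuracy for the item; the covariate is a per-item value
    (column name or Series indexed by item).  Fits the linear model
    ``accuracy ~ group + covariate + group:covariate`` with items as
    observations and returns the interaction F test.
    """
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    df = item_acc.copy()
    if isinstance(covariate, pd.Series):
        df["_cov"] = df[item].map(covariate)
    else:
        df["_cov"] = df[covariate]
    if df["_cov"].isna().any() or not np.isfinite(df["_cov"]).all():
        raise ValueError("covariate contains missing or non-finite values")
    if df["_cov"].nunique() < 2:
        raise ValueError("covariate is constant")
    df = df.rename(columns={dv: "_acc", group: "_grp"})
    fit = smf.ols("_acc ~ C(_grp) * _cov", data=df).fit()
    table = anova_lm(fit, typ=2)
    row = table.loc["C(_grp):_cov"]
    return TestResult(
        statistic=float(row["F"]),
        df=(float(row["df"]), float(table.loc["Residual", "df"])),
        p=float(row["PR(>F)"]),
        kind="F",
        tail="two",
        effect="group:covariate",
    )


def accuracy_covariate_correlations(
    acc: pd.DataFrame,
    covariates: pd.DataFrame,
    level: str = "participant",
    value: str = "correct",
) -> pd.DataFrame:
    """Item-wise correlations between accuracy and per-item covariates.

    ``covariates`` is indexed by item with one column per measure.

    * ``level='group'``: per-group item mean accuracy is correlated with
      each covariate; between-group difference scores (pairwise
      ``A-B`` rows) are included.
    * ``level='participant'``: per-participant item-wise point-biserial
      Pearson r with each covariate, returned with the Fisher z
      (atanh r).  |r| = 1 gives infinite z and a ``degenerate`` flag so
      downstream damage correlations can exclude it.
    """
    rows = []
    if level == "group":
        item_means = (
            acc.groupby(["group", "item"], observed=True)[value].mean().unstack("group")
        )
        series = {g: item_means[g] for g in item_means.columns}
        for a, b in itertools.combinations(sorted(series), 2):
            series[f"{a}-{b}"] = series[a] - series[b]
        for name, s in series.items():
            for cov in covariates.columns:
                joined = pd.concat([s, covariates[cov]], axis=1, join="inner").dropna()
                xx, yy = joined.iloc[:, 0], joined.iloc[:, 1]
                if len(joined) < 3 or xx.nunique() < 2 or yy.nunique() < 2:
                    r, p = np.nan, np.nan
                else:
                    r, p = stats.pearsonr(xx, yy)
                rows.append({"contrast": name, "covariate": cov, "r": r, "p": p,
                             "n": len(joined)})
        return pd.DataFrame(rows)

    if level != "participant":
        raise ValueError("level must be 'group' or 'participant'")
    has_group = "group" in acc.columns
    for pid, sub in acc.groupby("participant", observed=True):
        merged = sub.set_index("item").join(covariates, how="inner")
        for cov in covariates.columns:
            d = merged[[value, cov]].dropna()
            degenerate = False
            if len(d) < 3 or d[value].nunique() < 2 or d[cov].nunique() < 2:
                r, z = np.nan, np.nan
                degenerate = True
            else:
                r, _ = stats.pearsonr(d[value], d[cov])
                if abs(r) >= 1.0 - 1e-12:
                    z = np.inf * np.sign(r)
                    degenerate = True
                else:
                    z = float(np.arctanh(r))
            row = {"participant": pid, "covariate": cov, "r": r, "z": z,
                   "n": len(d), "degenerate": degenerate}
            if has_group:
                row["group"] = sub["group"].iloc[0]
            rows.append(row)
    return pd.DataFrame(rows)
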