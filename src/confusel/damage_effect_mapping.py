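"""Relating regional damage to behavioural effect scores.

Per-patient ROI damage proportions are correlated with per-patient
behavioural effect scores (e.g. living minus nonliving naming accuracy,
or the Fisher z of a participant's accuracy-covariate correlation) using
Spearman rank correlations, optionally partialling out a neighbouring
ROI's damage.  Cohorts in such studies are small (n = 6-8), so

* p-values default to the t approximation on mid-ranks, with an exact
  full-enumeration permutation option for n <= 8;
* tails are one-sided by declared direction (damage is predicted to
  lower accuracy, hence negative correlations with accuracy scores, and
  to raise positively-coded effect scores);
* ROIs in which fewer than ``min_nonzero`` patients have any damage are
  excluded from the correlation table (there is no rankable variation to
  interpret);
* no multiple-testing correction is applied by default (a Holm option
  exists).
"""

from __future__ import annotations

import itertools
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .behavioural_analysis import TestResult
from .lesion_quantification import DamageProfile, profiles_frame

__all__ = ["spearman", "partial_spearman", "damage_effect_table"]


def _check_tail(tail: str, direction: str) -> None:
    if tail not in ("one", "two"):
        raise ValueError("tail must be 'one' or 'two'")
    if direction not in ("positive", "negative"):
        raise ValueError("direction must be 'positive' or 'negative'")


def _t_approx_p(rho: float, n: int, tail: str, direction: str) -> float:
    if abs(rho) >= 1.0:
        p_two = 0.0
    else:
        t = rho * math.sqrt((n - 2) / (1.0 - rho**2))
        p_two = 2.0 * stats.t.sf(abs(t), n - 2)
    if tail == "two":
        return min(p_two, 1.0)
    hypothesised = rho if direction == "positive" else -rho
    p = p_two / 2.0 if hypothesised >= 0 else 1.0 - p_two / 2.0
    return min(p, 1.0)


def _rank_corr(x: np.ndarray, y: np.ndarray) -> float:
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def spearman(
    x,
    y,
    tail: str = "two",
    direction: str = "positive",
    exact: bool = False,
) -> TestResult:
    """Spearman rank correlation on mid-ranks.

    p comes from the t approximation with n-2 df, or with ``exact`` from
    full enumeration of the permutation null (n <= 8 only).  One-tailed p
    is taken in the hypothesised ``direction``.
    """
    _check_tail(tail, direction)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("vectors must have equal length")
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector has no rank correlation")
    rho = _rank_corr(x, y)

    flags: list[str] = []
    if exact:
        if n > 8:
            raise ValueError("exact permutation p available only for n <= 8")
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        rhos = np.array(
            [np.corrcoef(rx, perm)[0, 1] for perm in itertools.permutations(ry)]
        )
        eps = 1e-12
        if tail == "two":
            p = float(np.mean(np.abs(rhos) >= abs(rho) - eps))
        else:
            obs = rho if direction == "positive" else -rho
            signed = rhos if direction == "positive" else -rhos
            p = float(np.mean(signed >= obs - eps))
        flags.append("exact permutation p")
    else:
        p = _t_approx_p(rho, n, tail, direction)
    return TestResult(rho, float(n - 2), p, "rho", tail, "spearman", flags)


def partial_spearman(
    x,
    y,
    control,
    tail: str = "two",
    direction: str = "positive",
) -> TestResult:
    """First-order partial Spearman correlation.

    All three vectors are rank-transformed (mid-ranks), then the
    first-order partial Pearson correlation

        r_xy.c = (r_xy - r_xc r_yc) / sqrt((1 - r_xc^2)(1 - r_yc^2))

    is computed on the ranks.  df = n - 3; p via the t approximation with
    the declared tail.  A control perfectly collinear on ranks with x or y
    is an error (the partial correlation is undefined).
    """
    _check_tail(tail, direction)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    c = np.asarray(control, dtype=float)
    if not (len(x) == len(y) == len(c)):
        raise ValueError("vectors must have equal length")
    n = len(x)
    if n < 5:
        raise ValueError("need at least 5 observations")
    for name, v in (("x", x), ("y", y), ("control", c)):
        if np.ptp(v) == 0:
            raise ValueError(f"constant vector: {name}")
    r_xy = _rank_corr(x, y)
    r_xc = _rank_corr(x, c)
    r_yc = _rank_corr(y, c)
    denom = (1.0 - r_xc**2) * (1.0 - r_yc**2)
    if denom <= 1e-12:
        raise ValueError("control is collinear with x or y on ranks")
    rho = (r_xy - r_xc * r_yc) / math.sqrt(denom)
    rho = float(np.clip(rho, -1.0, 1.0))
    df = n - 3
    if abs(rho) >= 1.0:
        p_two = 0.0
    else:
        t = rho * math.sqrt(df / (1.0 - rho**2))
        p_two = 2.0 * stats.t.sf(abs(t), df)
    if tail == "two":
        p = min(p_two, 1.0)
    else:
        hypothesised = rho if direction == "positive" else -rho
        p = p_two / 2.0 if hypothesised >= 0 else 1.0 - p_two / 2.0
    return TestResult(rho, float(df), float(min(p, 1.0)), "rho", tail, "partial spearman")


def _holm(pvals: np.ndarray) -> np.ndarray:
    order = np.argsort(pvals)
    m = np.sum(~np.isnan(pvals))
    adj = np.full_like(pvals, np.nan)
    running = 0.0
    rank = 0
    for i in order:
        if np.isnan(pvals[i]):
            continue
        running = max(running, (m - rank) * pvals[i])
        adj[i] = min(running, 1.0)
        rank += 1
    return adj


def damage_effect_table(
    profiles: Sequence[DamageProfile] | pd.DataFrame,
    effects: pd.DataFrame,
    directions: Mapping[str, str] | str = "negative",
    tail: str = "one",
    control: str | None = None,
    alpha: float = 0.05,
    min_nonzero: int = 3,
    exact: bool = False,
    holm: bool = False,
) -> pd.DataFrame:
    """ROI x effect table of (partial) Spearman correlations.

    ``effects`` is indexed by patient with one column per named effect
    score; ``directions`` gives each effect's hypothesised correlation
    sign with damage ('negative' for accuracy scores, 'positive' for
    damage-increases-effect scores), or a single value for all.  ROIs
    where fewer than ``min_nonzero`` patients have nonzero damage are
    excluded (reported with NaN and an ``excluded`` flag).  With
    ``control``, that ROI's damage is partialled out of every other ROI's
    correlations.  Rows with non-finite effect scores are dropped per
    effect.  Patient ids must align between profiles and effects.
    """
    if isinstance(profiles, pd.DataFrame):
        dmg = profiles.drop(columns=["lesion_volume_cm3"], errors="ignore")
    else:
        dmg = profiles_frame(profiles).drop(columns="lesion_volume_cm3")
    missing = set(effects.index) - set(dmg.index)
    if missing:
        raise ValueError(f"patients missing damage profiles: {sorted(missing)}")
    dmg = dmg.loc[effects.index]

    rows = []
    for roi in dmg.columns:
        d = dmg[roi].to_numpy(float)
        excluded = int(np.sum(d > 0)) < min_nonzero
        for eff in effects.columns:
            direction = directions if isinstance(directions, str) else directions[eff]
            e = effects[eff].to_numpy(float)
            ok = np.isfinite(e) & np.isfinite(d)
            row = {"roi": roi, "effect": eff, "n": int(ok.sum()),
                   "excluded": excluded, "partial": False}
            if excluded or ok.sum() < 4 or np.ptp(d[ok]) == 0 or np.ptp(e[ok]) == 0:
                row.update(rho=np.nan, p=np.nan)
            elif control is not None and roi != control:
                res = partial_spearman(d[ok], e[ok], dmg[control].to_numpy(float)[ok],
                                       tail=tail, direction=direction)
                row.update(rho=res.statistic, p=res.p, partial=True)
            else:
                res = spearman(d[ok], e[ok], tail=tail, direction=direction, exact=exact)
                row.update(rho=res.statistic, p=res.p)
            rows.append(row)
    out = pd.DataFrame(rows)
    if holm:
        out["p"] = _holm(out["p"].to_numpy(float))
    out["significant"] = pd.array(out["p"] < alpha, dtype="boolean")
    out.loc[out["p"].isna(), "significant"] = pd.NA
    return out
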