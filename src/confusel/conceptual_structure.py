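"""Conceptual-structure statistics from semantic property norms.

Property norms list, for each concept, the features participants produced
for it together with a production frequency (how many participants listed
the feature).  From the resulting concept x feature count matrix this
module computes the feature-based statistics of the Conceptual Structure
Account:

* feature **distinctiveness** — the inverse of the number of concepts a
  feature occurs in (a feature unique to one concept is maximally
  distinctive, d = 1);
* **shared** features — features occurring in at least ``min_shared``
  concepts (3 by convention);
* **correlational strength** — the mean of the significant pairwise
  Pearson correlations between shared features' production-frequency
  columns, at the feature level and averaged within a concept;
* **correlation x distinctiveness** — per concept, the unstandardised OLS
  slope of feature correlational strength regressed on feature
  distinctiveness, a measure on which confusable concepts (typically
  living things) score low;
* **cosine similarity** between two concepts' production-frequency
  vectors, the semantic-distance measure used to build close/distant
  word-picture pairs.

Undefined statistics are represented as NaN and never silently coerced to
zero, except under the documented ``undefined_strength_as_zero`` flag of
:func:`concept_statistics`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PropertyNorms",
    "FeatureStats",
    "ConceptStats",
    "PairDistance",
    "load_property_norms",
    "feature_statistics",
    "concept_statistics",
    "cosine_similarity",
    "pair_condition_summary",
    "inverse_concept_count",
]

DEFAULT_MIN_SHARED = 3
DEFAULT_ALPHA = 0.05


def inverse_concept_count(n_concepts: np.ndarray) -> np.ndarray:
    """Default distinctiveness formula: d = 1 / (number of concepts listing
    the feature), hence d in (0, 1] and strictly decreasing in the count."""
    n = np.asarray(n_concepts, dtype=float)
    with np.errstate(divide="ignore"):
        return np.where(n > 0, 1.0 / n, np.nan)


@dataclass
class PropertyNorms:
    """A concept x feature production-frequency matrix with domain labels.

    Parameters
    ----------
    concepts, features
        Unique labels; exact string matching, no normalisation.
    pf
        Non-negative integer matrix, shape ``(len(concepts), len(features))``.
        ``pf[i, j]`` is the number of norming participants who produced
        feature ``j`` for concept ``i`` (0 when the pair was never produced).
    domain, category
        Optional per-concept labels (e.g. living/nonliving; animal, tool...).
    """

    concepts: list[str]
    features: list[str]
    pf: np.ndarray
    domain: list[str] | None = None
    category: list[str] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pf = np.asarray(self.pf)
        if self.pf.shape != (len(self.concepts), len(self.features)):
            raise ValueError(
                f"pf shape {self.pf.shape} does not match "
                f"{len(self.concepts)} concepts x {len(self.features)} features"
            )
        if np.any(self.pf < 0):
            raise ValueError("production frequencies must be non-negative")
        if len(set(self.concepts)) != len(self.concepts):
            raise ValueError("concept labels must be unique")
        if len(set(self.features)) != len(self.features):
            raise ValueError("feature labels must be unique")
        if self.pf.shape[0] and np.any((self.pf > 0).sum(axis=1) == 0):
            empty = [c for c, row in zip(self.concepts, self.pf) if not (row > 0).any()]
            raise ValueError(f"concepts with no features: {empty}")
        for name in ("domain", "category"):
            labels = getattr(self, name)
            if labels is not None and len(labels) != len(self.concepts):
                raise ValueError(f"{name} labels must match number of concepts")
        self._concept_index = {c: i for i, c in enumerate(self.concepts)}

    @property
    def n_concepts(self) -> int:
        return len(self.concepts)

    @property
    def n_features(self) -> int:
        return len(self.features)

    def vector(self, concept: str) -> np.ndarray:
        """Production-frequency vector of one concept over all features."""
        try:
            i = self._concept_index[concept]
        except KeyError:
            raise KeyError(f"unknown concept: {concept!r}") from None
        return self.pf[i]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.pf, index=self.concepts, columns=self.features)


@dataclass
class FeatureStats:
    feature: str
    n_concepts: int
    distinctiveness: float
    is_shared: bool
    correlational_strength: float  # NaN when undefined


@dataclass
class ConceptStats:
    concept: str
    mean_distinctiveness: float
    correlational_strength: float  # NaN when undefined
    corr_x_dist_slope: float       # NaN when undefined
    n_features: int
    n_shared_features: int


@dataclass
class PairDistance:
    """A word-picture stimulus pair with its cosine semantic distance."""
    word_concept: str
    picture_concept: str
    cosine: float
    condition: str  # close | distant
    domain: str     # living | nonliving


def load_property_norms(path, sep: str | None = None, strip: bool = False) -> PropertyNorms:
    """Read long-format norms ``concept,feature,production_frequency`` from a
    delimited text file (CSV or TSV; the delimiter is sniffed when ``sep`` is
    None).  Optional ``domain``/``category`` columns are carried through.

    Absent concept-feature pairs become zeros in the assembled matrix.
    Duplicate (concept, feature) rows and negative or non-numeric
    frequencies are format errors.
    """
    df = pd.read_csv(path, sep=sep, engine="python")
    if df.empty:
        raise ValueError("no records in norms file")
    required = {"concept", "feature", "production_frequency"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"norms file missing columns: {sorted(missing)}")
    if strip:
        df["concept"] = df["concept"].astype(str).str.strip()
        df["feature"] = df["feature"].astype(str).str.strip()
    pf_col = pd.to_numeric(df["production_frequency"], errors="coerce")
    if pf_col.isna().any():
        bad = df.loc[pf_col.isna(), ["concept", "feature"]].iloc[0]
        raise ValueError(
            f"non-numeric production_frequency for ({bad['concept']},{bad['feature']})"
        )
    if (pf_col < 0).any():
        bad = df.loc[pf_col < 0, ["concept", "feature"]].iloc[0]
        raise ValueError(
            f"negative production_frequency for ({bad['concept']},{bad['feature']})"
        )
    dup = df.duplicated(subset=["concept", "feature"], keep=False)
    if dup.any():
        pairs = sorted(
            set(map(tuple, df.loc[dup, ["concept", "feature"]].values))
        )
        listing = "; ".join(f"{c},{f}" for c, f in pairs)
        raise ValueError(f"duplicate (concept,feature) rows: {listing}")

    df = df.assign(production_frequency=pf_col)
    mat = df.pivot(index="concept", columns="feature", values="production_frequency")
    mat = mat.fillna(0.0)
    concepts = list(mat.index)
    features = list(mat.columns)

    def _per_concept(col: str) -> list[str] | None:
        if col not in df.columns:
            return None
        m = df.groupby("concept")[col].first()
        return [m.get(c) for c in concepts]

    return PropertyNorms(
        concepts=concepts,
        features=features,
        pf=mat.to_numpy(),
        domain=_per_concept("domain"),
        category=_per_concept("category"),
    )


# ---------------------------------------------------------------------------
# pairwise feature correlations
# ---------------------------------------------------------------------------

def _shared_pair_correlations(
    norms: PropertyNorms,
    shared_idx: np.ndarray,
    alpha: float,
    positive_only: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r between shared features' pf columns (across all concepts),
    and the boolean retention mask (p < alpha, and r > 0 when positive_only).

    Returns (r, retained), both (k, k) with the diagonal not retained.
    Constant columns yield NaN correlations, never retained.
    """
    n = norms.n_concepts
    if n < 2:
        raise ValueError("need at least two concepts to correlate features")
    cols = norms.pf[:, shared_idx].astype(float)
    k = cols.shape[1]
    if k == 0:
        return np.zeros((0, 0)), np.zeros((0, 0), dtype=bool)
    centred = cols - cols.mean(axis=0)
    ss = np.sqrt((centred ** 2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (centred.T @ centred) / np.outer(ss, ss)
    r = np.clip(r, -1.0, 1.0)
    # two-sided p via the exact t transform of Pearson's r
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    p = np.where(np.isclose(np.abs(r), 1.0), 0.0, p)
    retained = np.isfinite(r) & (p < alpha)
    if positive_only:
        retained &= r > 0
    np.fill_diagonal(retained, False)
    return r, retained


def feature_statistics(
    norms: PropertyNorms,
    min_shared: int = DEFAULT_MIN_SHARED,
    alpha: float = DEFAULT_ALPHA,
    positive_only: bool = True,
    distinctiveness_fn: Callable[[np.ndarray], np.ndarray] = inverse_concept_count,
) -> list[FeatureStats]:
    """Per-feature distinctiveness, sharedness and correlational strength.

    A feature's correlational strength is the mean of its retained pairwise
    Pearson correlations (p < ``alpha``, positive when ``positive_only``)
    with all other shared features, the correlations being computed across
    all concepts' production-frequency columns.  It is NaN for non-shared
    features and for shared features with no retained partner.
    """
    if min_shared < 2:
        raise ValueError("min_shared must be >= 2")
    if min_shared > norms.n_concepts:
        raise ValueError(
            f"min_shared={min_shared} exceeds number of concepts ({norms.n_concepts})"
        )
    if norms.n_concepts < 2:
        raise ValueError("cannot compute feature statistics for a single concept")

    counts = (norms.pf > 0).sum(axis=0)
    dist = distinctiveness_fn(counts)
    is_shared = counts >= min_shared
    shared_idx = np.flatnonzero(is_shared)

    strength = np.full(norms.n_features, np.nan)
    if shared_idx.size >= 2:
        r, retained = _shared_pair_correlations(norms, shared_idx, alpha, positive_only)
        n_ret = retained.sum(axis=1)
        with np.errstate(invalid="ignore"):
            mean_r = np.where(n_ret > 0, np.where(retained, r, 0.0).sum(axis=1), np.nan)
        strength[shared_idx] = np.where(n_ret > 0, mean_r / np.maximum(n_ret, 1), np.nan)

    return [
        FeatureStats(
            feature=f,
            n_concepts=int(counts[j]),
            distinctiveness=float(dist[j]),
            is_shared=bool(is_shared[j]),
            correlational_strength=float(strength[j]),
        )
        for j, f in enumerate(norms.features)
    ]


def concept_statistics(
    norms: PropertyNorms,
    fstats: Sequence[FeatureStats],
    alpha: float = DEFAULT_ALPHA,
    positive_only: bool = True,
    undefined_strength_as_zero: bool = True,
) -> list[ConceptStats]:
    """Per-concept mean distinctiveness, correlational strength and the
    correlation x distinctiveness slope.

    ``fstats`` must come from :func:`feature_statistics` on the same norms
    with the same ``alpha``/``positive_only`` settings (pair retention is
    recomputed here for the concept-level average).

    * mean_distinctiveness — mean distinctiveness of the concept's features
      (those with pf > 0).
    * correlational_strength — mean over retained pairwise correlations
      whose *both* features are shared features of this concept; NaN when
      the concept has no such pair.
    * corr_x_dist_slope — unstandardised OLS slope of feature-level
      correlational strength on feature distinctiveness over the concept's
      features.  Features with undefined strength enter with strength 0
      when ``undefined_strength_as_zero`` (default; non-shared features are
      exactly the weakly-correlated end the measure contrasts), otherwise
      they are excluded.  NaN when fewer than two usable features remain or
      the distinctiveness values have zero variance.
    """
    if len(fstats) != norms.n_features:
        raise ValueError("fstats does not match the norms' features")
    dist = np.array([fs.distinctiveness for fs in fstats])
    fstrength = np.array([fs.correlational_strength for fs in fstats])
    is_shared = np.array([fs.is_shared for fs in fstats])
    shared_idx = np.flatnonzero(is_shared)
    pos_in_shared = {j: k for k, j in enumerate(shared_idx)}

    if shared_idx.size >= 2 and norms.n_concepts >= 2:
        r, retained = _shared_pair_correlations(norms, shared_idx, alpha, positive_only)
    else:
        k = shared_idx.size
        r = np.zeros((k, k))
        retained = np.zeros((k, k), dtype=bool)

    out = []
    present = norms.pf > 0
    for i, concept in enumerate(norms.concepts):
        feat_idx = np.flatnonzero(present[i])
        mean_dist = float(dist[feat_idx].mean())

        # concept-level strength: pairs within this concept's shared features
        cshared = [pos_in_shared[j] for j in feat_idx if is_shared[j]]
        strength = np.nan
        if len(cshared) >= 2:
            sub = np.ix_(cshared, cshared)
            ret = retained[sub]
            if ret.any():
                strength = float(r[sub][ret].mean())  # each unordered pair counted once per direction; symmetric -> same mean

        # slope of feature strength on feature distinctiveness
        y = fstrength[feat_idx].copy()
        x = dist[feat_idx].copy()
        if undefined_strength_as_zero:
            y = np.where(np.isnan(y), 0.0, y)
        usable = ~np.isnan(y) & ~np.isnan(x)
        x, y = x[usable], y[usable]
        slope = np.nan
        if x.size >= 2 and np.ptp(x) > 0:
            xc = x - x.mean()
            slope = float((xc @ (y - y.mean())) / (xc @ xc))

        out.append(
            ConceptStats(
                concept=concept,
                mean_distinctiveness=mean_dist,
                correlational_strength=strength,
                corr_x_dist_slope=slope,
                n_features=int(feat_idx.size),
                n_shared_features=int(len(cshared)),
            )
        )
    return out


def cosine_similarity(norms: PropertyNorms, a: str, b: str) -> float:
    """Cosine between two concepts' production-frequency vectors, in [0, 1]
    for non-negative vectors; 1 iff the vectors are proportional."""
    va, vb = norms.vector(a).astype(float), norms.vector(b).astype(float)
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0 or nb == 0:
        which = a if na == 0 else b
        raise ValueError(f"empty concept vector: {which!r}")
    return float(va @ vb / (na * nb))


def pair_condition_summary(pairs: Sequence[PairDistance]) -> pd.DataFrame:
    """Mean/SD/n of cosine distance per condition x domain cell, for checking
    stimulus-set construction (close pairs should far exceed distant ones,
    matched across domains).  Cells with no pairs are flagged empty."""
    if not pairs:
        raise ValueError("no pairs supplied")
    df = pd.DataFrame(
        {
            "condition": [p.condition for p in pairs],
            "domain": [p.domain for p in pairs],
            "cosine": [p.cosine for p in pairs],
        }
    )
    g = df.groupby(["condition", "domain"])["cosine"]
    summary = g.agg(mean="mean", sd=lambda s: s.std(ddof=1), n="count").reset_index()
    full = summary.set_index(["condition", "domain"]).reindex(
        pd.MultiIndex.from_product(
            [sorted(df["condition"].unique()), sorted(df["domain"].unique())],
            names=["condition", "domain"],
        )
    )
    full["n"] = full["n"].fillna(0).astype(int)
    full["empty"] = full["n"] == 0
    return full.reset_index()


def feature_stats_frame(fstats: Sequence[FeatureStats]) -> pd.DataFrame:
    return pd.DataFrame([vars(fs) for fs in fstats])


def concept_stats_frame(cstats: Sequence[ConceptStats]) -> pd.DataFrame:
    return pd.DataFrame([vars(cs) for cs in cstats])
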