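"""Synthetic property norms, lesion cohorts and behavioural responses.

Every pipeline stage in this package can be exercised without access to
the real property norms or patient images: the generators here produce
inputs with *known ground truth* in the same schemas the analysis modules
read, and :func:`load_fixture` returns the per-patient summary tables of
the study (demographics/lesion volumes, naming accuracy by category,
word-picture matching accuracy) packaged as CSV.

Generators are pure functions of (config, seed): the same seed yields
byte-identical output.

The norms generator emulates the key structural property of real norms —
living concepts carry more shared features (those occurring in >= 3
concepts) than nonliving ones, with target per-domain means of 12.7 and
11.1 shared features per concept.  Assignment is deficit-greedy: shared
features are created one at a time, each reused by 3-5 concepts chosen to
keep per-concept counts close to the domain target, so realised means hit
the targets to within rounding.  Production frequencies are truncated
geometric counts on {1..30}, small positive integers as in real norms.

The lesion generator fills disjoint ROI boxes in raster order to the
requested damage fraction (rounded to voxel resolution), so the realised
fraction it records as ground truth is exactly what
:func:`~confusel.lesion_quantification.roi_damage_profile` must recover.

The behavioural generator draws per-trial Bernoulli responses with

    logit P(correct) = beta0 + beta_dmg * d_p + beta_int * d_p * s_i (+ noise)

where ``d_p`` is the participant's damage fraction in the behaviourally
critical ROI (perirhinal cortex by default) and ``s_i`` the item's
standardised correlation x distinctiveness slope, the structure behind a
damage-modulated accuracy-structure correlation.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .conceptual_structure import PropertyNorms, concept_statistics, feature_statistics
from .lesion_quantification import BinaryMask, DamageProfile, ROIAtlas

__all__ = [
    "NormGenConfig",
    "CohortGenConfig",
    "gen_property_norms",
    "gen_lesion_cohort",
    "gen_behaviour",
    "load_fixture",
    "default_roi_boxes",
    "default_damage_fractions",
]

FIXTURES = ("table1_volumes", "table4_naming", "table8_wpm")


@dataclass
class NormGenConfig:
    """Configuration for the property-norms generator.

    ``mean_shared`` gives the target mean number of shared features per
    concept in each domain; the defaults reproduce the living/nonliving
    asymmetry of real norms (12.7 vs 11.1).
    """

    n_living: int = 30
    n_nonliving: int = 30
    mean_shared_living: float = 12.7
    mean_shared_nonliving: float = 11.1
    distinctive_per_concept: int = 5
    shared_pool_size: int = 400
    reuse_min: int = 3
    reuse_max: int = 5
    pf_geom_p: float = 0.25
    pf_max: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_living < 0 or self.n_nonliving < 0 or self.n_living + self.n_nonliving == 0:
            raise ValueError("need a positive number of concepts")
        if self.reuse_min < 3:
            raise ValueError("shared features must be reusable by >= 3 concepts")
        if self.distinctive_per_concept < 1:
            raise ValueError("each concept needs at least one distinctive feature")


@dataclass
class CohortGenConfig:
    """Configuration for the lesion cohort and behavioural generators."""

    grid_shape: tuple[int, int, int] = (32, 32, 16)
    voxel_dims: tuple[float, float, float] = (1.0, 1.0, 1.0)
    roi_boxes: dict = field(default_factory=lambda: default_roi_boxes())
    damage_fractions: pd.DataFrame | None = None  # patients x ROI targets
    behaviour_roi: str = "PRc"
    beta0: float = 2.75
    beta_dmg: float = -3.0
    beta_int: float = 3.0
    noise_sd: float = 0.0
    participant_sd: float = 0.0
    stochastic_placement: bool = False
    seed: int = 0


def default_roi_boxes() -> dict[str, tuple]:
    """Disjoint box layout for the six anterior-temporal ROIs on the
    default 32 x 32 x 16 grid (half-open index ranges)."""
    return {
        "TPole": ((2, 8), (24, 30), (4, 10)),
        "PRc": ((10, 15), (14, 24), (4, 9)),
        "ERc": ((16, 20), (14, 22), (4, 9)),
        "Fusiform": ((10, 15), (4, 14), (4, 9)),
        "ITG": ((21, 26), (4, 24), (4, 9)),
        "MTG": ((27, 31), (4, 24), (4, 9)),
    }


def default_damage_fractions(n_patients: int = 8) -> pd.DataFrame:
    """Default per-patient target damage fractions: perirhinal damage
    spanning 0..0.7 with partially co-varying neighbouring damage."""
    pats = [f"S{i+1}" for i in range(n_patients)]
    prc = np.round(np.arange(n_patients) * 0.1, 10)
    fus = np.round((np.arange(n_patients) % 4) * 0.15, 10)
    itg = np.round(((n_patients - 1 - np.arange(n_patients)) % 5) * 0.1, 10)
    df = pd.DataFrame(
        {
            "TPole": np.where(np.arange(n_patients) % 3 == 0, 0.2, 0.0),
            "PRc": prc,
            "ERc": 0.0,
            "Fusiform": fus,
            "ITG": itg,
            "MTG": np.round(itg * 0.5, 10),
        },
        index=pd.Index(pats, name="patient"),
    )
    return df


# ---------------------------------------------------------------------------
# property norms
# ---------------------------------------------------------------------------

def _truncated_geometric(rng: np.random.Generator, p: float, kmax: int, size: int) -> np.ndarray:
    """Inverse-CDF sample from a geometric distribution on {1..kmax}."""
    u = rng.random(size)
    tail = (1.0 - p) ** kmax
    k = np.ceil(np.log1p(-u * (1.0 - tail)) / np.log1p(-p))
    return np.clip(k.astype(int), 1, kmax)


def _assign_shared(
    rng: np.random.Generator, n_concepts: int, mean_shared: float, reuse_min: int, reuse_max: int
) -> list[list[int]]:
    """Feature -> concept-index lists such that every feature is used by
    reuse_min..reuse_max concepts and total slots = round(n * mean)."""
    if n_concepts == 0:
        return []
    total = int(round(n_concepts * mean_shared))
    if n_concepts < reuse_min:
        raise ValueError(
            f"domain has {n_concepts} concepts; shared features need >= {reuse_min}"
        )
    counts = np.zeros(n_concepts)
    members: list[list[int]] = []
    remaining = total
    while remaining >= reuse_min:
        k = min(int(rng.integers(reuse_min, reuse_max + 1)), remaining, n_concepts)
        if k < reuse_min:
            break
        deficit = mean_shared - counts + rng.random(n_concepts) * 1e-6  # random tie-break
        chosen = np.argsort(-deficit)[:k]
        members.append(sorted(int(c) for c in chosen))
        counts[chosen] += 1
        remaining -= k
    while remaining > 0 and members:
        # top up by widening an existing shared feature to one more concept
        deficit = mean_shared - counts + rng.random(n_concepts) * 1e-6
        for c in np.argsort(-deficit):
            feats = [i for i, mem in enumerate(members) if int(c) not in mem]
            if feats:
                i = int(rng.choice(feats))
                members[i].append(int(c))
                members[i].sort()
                counts[c] += 1
                remaining -= 1
                break
        else:  # pragma: no cover - every concept in every feature
            break
    return members


def gen_property_norms(cfg: NormGenConfig, seed: int | None = None) -> PropertyNorms:
    """Generate synthetic property norms with known shared-feature counts.

    The returned norms carry ground truth in ``meta``:
    ``shared_count[concept]`` (number of shared features the generator gave
    the concept) and the realised per-domain means.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    domains = []
    if cfg.n_living:
        domains.append(("living", cfg.n_living, cfg.mean_shared_living))
    if cfg.n_nonliving:
        domains.append(("nonliving", cfg.n_nonliving, cfg.mean_shared_nonliving))

    concepts: list[str] = []
    domain_labels: list[str] = []
    category_labels: list[str] = []
    feature_members: dict[str, list[int]] = {}  # feature -> global concept indices
    shared_counts: dict[str, int] = {}
    cats = {"living": ("animal", "fruit_veg"), "nonliving": ("tool", "vehicle")}

    n_shared_total = 0
    for dom, n, mean_shared in domains:
        offset = len(concepts)
        names = [f"{dom}_{i:03d}" for i in range(n)]
        concepts.extend(names)
        domain_labels.extend([dom] * n)
        category_labels.extend(rng.choice(cats[dom], size=n).tolist())
        members = _assign_shared(rng, n, mean_shared, cfg.reuse_min, cfg.reuse_max)
        n_shared_total += len(members)
        if n_shared_total > cfg.shared_pool_size:
            raise ValueError(
                f"shared pool too small: need > {cfg.shared_pool_size} shared features"
            )
        counts = np.zeros(n, dtype=int)
        for j, mem in enumerate(members):
            feature_members[f"shared_{dom}_{j:04d}"] = [offset + c for c in mem]
            counts[mem] += 1
        for name, c in zip(names, counts):
            shared_counts[name] = int(c)

    for gi, cname in enumerate(concepts):
        for d in range(cfg.distinctive_per_concept):
            feature_members[f"dist_{cname}_{d}"] = [gi]

    features = list(feature_members)
    pf = np.zeros((len(concepts), len(features)), dtype=int)
    for j, f in enumerate(features):
        mem = feature_members[f]
        pf[mem, j] = _truncated_geometric(rng, cfg.pf_geom_p, cfg.pf_max, len(mem))

    realised = {
        dom: float(np.mean([shared_counts[c] for c, d in zip(concepts, domain_labels) if d == dom]))
        for dom, _, _ in domains
    }
    return PropertyNorms(
        concepts=concepts,
        features=features,
        pf=pf,
        domain=domain_labels,
        category=category_labels,
        meta={
            "seed": cfg.seed if seed is None else seed,
            "shared_count": shared_counts,
            "realised_mean_shared": realised,
        },
    )


# ---------------------------------------------------------------------------
# lesion cohort
# ---------------------------------------------------------------------------

def gen_lesion_cohort(
    cfg: CohortGenConfig, seed: int | None = None
) -> tuple[ROIAtlas, list[BinaryMask], list[DamageProfile]]:
    """Build a box-layout ROI atlas and per-patient lesion masks hitting the
    target damage fractions, returning the exactly realised fractions as
    ground-truth DamageProfiles.

    Placement is deterministic (raster order within each ROI) unless
    ``stochastic_placement``; either way the realised fraction equals the
    rounded voxel count divided by the ROI size.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    shape = tuple(cfg.grid_shape)
    labels = np.zeros(shape, dtype=int)
    legend: dict[int, str] = {}
    voxels: dict[str, np.ndarray] = {}
    for code, (name, ((x0, x1), (y0, y1), (z0, z1))) in enumerate(cfg.roi_boxes.items(), 1):
        box = np.zeros(shape, dtype=bool)
        box[x0:x1, y0:y1, z0:z1] = True
        if (labels[box] != 0).any():
            raise ValueError(f"ROI boxes overlap at {name!r}")
        labels[box] = code
        legend[code] = name
        voxels[name] = np.flatnonzero(box.ravel())
    atlas = ROIAtlas(labels=labels, legend=legend, voxel_dims=cfg.voxel_dims)

    fractions = cfg.damage_fractions
    if fractions is None:
        fractions = default_damage_fractions()
    unknown = set(fractions.columns) - set(voxels)
    if unknown:
        raise ValueError(f"damage fractions for unknown ROIs: {sorted(unknown)}")

    masks, profiles = [], []
    for patient, row in fractions.iterrows():
        flat = np.zeros(int(np.prod(shape)), dtype=np.uint8)
        realised: dict[str, float] = {name: 0.0 for name in voxels}
        for roi, target in row.items():
            if not 0.0 <= target <= 1.0:
                raise ValueError(f"target fraction out of [0,1] for {patient}/{roi}")
            size = voxels[roi].size
            m = int(round(target * size))
            if abs(m - target * size) > 1.0:
                raise ValueError(
                    f"target fraction {target} unachievable for {roi} at grid resolution"
                )
            if m > 0:
                order = voxels[roi]
                if cfg.stochastic_placement:
                    order = rng.permutation(order)
                flat[order[:m]] = 1
            realised[roi] = m / size
        mask = BinaryMask(data=flat.reshape(shape), voxel_dims=cfg.voxel_dims)
        volume = float(flat.sum()) * mask.voxel_volume_mm3 / 1000.0
        masks.append(mask)
        profiles.append(
            DamageProfile(patient=str(patient), damage=realised, lesion_volume_cm3=volume)
        )
    return atlas, masks, profiles


# ---------------------------------------------------------------------------
# behaviour
# ---------------------------------------------------------------------------

def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def standardised_slopes(norms: PropertyNorms) -> pd.Series:
    """Per-concept correlation x distinctiveness slopes, z-scored across the
    concepts for which the slope is defined (NaN slopes are dropped)."""
    fstats = feature_statistics(norms)
    cstats = concept_statistics(norms, fstats)
    s = pd.Series(
        {c.concept: c.corr_x_dist_slope for c in cstats}, name="corr_x_dist"
    ).dropna()
    sd = s.std(ddof=0)
    if len(s) < 2 or sd == 0:
        raise ValueError("cannot standardise: fewer than two defined slopes")
    return (s - s.mean()) / sd


def gen_behaviour(
    norms: PropertyNorms,
    profiles: Sequence[DamageProfile] | Mapping[str, float] | pd.Series,
    cfg: CohortGenConfig,
    seed: int | None = None,
    slopes: pd.Series | None = None,
) -> pd.DataFrame:
    """Simulate per-participant, per-item correctness.

    P(correct) follows a logistic model in the participant's damage to
    ``cfg.behaviour_roi`` and its interaction with the item's standardised
    correlation x distinctiveness slope.  ``profiles`` may be
    DamageProfiles or a patient -> damage-fraction mapping.  Pass
    precomputed ``slopes`` (from :func:`standardised_slopes`) to skip the
    concept-statistics step in repeated simulations.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    if isinstance(profiles, (pd.Series, Mapping)):
        damage = pd.Series(profiles, dtype=float)
    else:
        damage = pd.Series(
            {p.patient: p.damage[cfg.behaviour_roi] for p in profiles}, dtype=float
        )
    if not np.isfinite(damage).all():
        raise ValueError("non-finite damage covariate")
    if slopes is None:
        slopes = standardised_slopes(norms)
    if not np.isfinite(slopes).all():
        raise ValueError("non-finite item covariate")

    items = list(slopes.index)
    s = slopes.to_numpy(float)
    rows = []
    for patient, d in damage.items():
        logit = cfg.beta0 + cfg.beta_dmg * d + cfg.beta_int * d * s
        if cfg.participant_sd > 0:
            logit = logit + rng.normal(0.0, cfg.participant_sd)
        if cfg.noise_sd > 0:
            logit = logit + rng.normal(0.0, cfg.noise_sd, size=len(s))
        correct = (rng.random(len(s)) < _logistic(logit)).astype(int)
        group = "vATL-damaged" if d > 0 else "vATL-intact"
        rows.append(
            pd.DataFrame(
                {
                    "participant": patient,
                    "group": group,
                    "item": items,
                    "correct": correct,
                    "damage": d,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# packaged fixtures
# ---------------------------------------------------------------------------

def load_fixture(name: str) -> pd.DataFrame:
    """Return one of the packaged per-patient summary tables.

    ``table1_volumes`` — demographics and lesion volumes (14 patients).
    ``table4_naming`` — naming accuracy (%) by object category; per-patient
    rows plus the printed group mean/SEM rows (``row_type`` column; the
    control group exists only as printed summaries).
    ``table8_wpm`` — word-picture matching accuracy (%) for close/distant
    x living/nonliving conditions, same layout.
    """
    if name not in FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; available: {FIXTURES}")
    ref = importlib.resources.files("confusel").joinpath(f"data/{name}.csv")
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path)
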