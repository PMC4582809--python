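"""Lesion masks, ROI atlases and per-ROI damage quantification.

The workflow mirrors a standard ROI-based lesion study of the anterior
temporal lobe: lesions are traced in native space, warped to a common
space (MNI) upstream of this module, then

1. the interpolated warped mask is re-binarised at a 0.5 threshold
   (:func:`binarize_mask`);
2. manual ROI drawings from several raters are combined into per-ROI
   probability maps and a maximum-probability label atlas, ties left
   undefined (:func:`build_max_prob_atlas`), with lateral ROIs optionally
   truncated posteriorly at the reference ROI's posterior limit
   (:func:`truncate_posterior`);
3. each patient's damage is summarised as the proportion of each ROI's
   voxels inside the binary lesion (:func:`roi_damage_profile`), together
   with total lesion volume in cm^3;
4. pairwise Pearson correlations between ROIs' damage scores across the
   cohort quantify how independent the regional measures are
   (:func:`damage_intercorrelations`).

Grids must match exactly between lesion and atlas: resampling belongs to
the upstream spatial-normalisation step, not here.  Volumes are read and
written as NIfTI via nibabel; label legends travel as sidecar TSVs.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "VolumeGrid",
    "BinaryMask",
    "ROIAtlas",
    "DamageProfile",
    "binarize_mask",
    "build_max_prob_atlas",
    "truncate_posterior",
    "roi_damage_profile",
    "damage_intercorrelations",
    "read_volume",
    "write_volume",
    "read_atlas",
    "write_atlas",
]

#: axis index of the anterior-posterior direction in the stored arrays.
AP_AXIS = 1


@dataclass
class VolumeGrid:
    """A 3-D scalar volume on a regular grid.

    ``orientation`` records the anatomical sense of the axes; under the
    default "RAS" convention axis 1 is anterior-posterior with *posterior =
    decreasing index*, which :func:`truncate_posterior` consults.
    """

    data: np.ndarray
    voxel_dims: tuple[float, float, float] = (1.0, 1.0, 1.0)
    space_id: str = "MNI"
    orientation: str = "RAS"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("volume data must be 3-D")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")
        if len(self.voxel_dims) != 3 or any(d <= 0 for d in self.voxel_dims):
            raise ValueError("voxel dimensions must be three positive numbers")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.voxel_dims
        return dx * dy * dz


@dataclass
class BinaryMask(VolumeGrid):
    """A VolumeGrid restricted to {0, 1}: damaged voxels 1, intact 0."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if not np.isin(self.data, (0, 1)).all():
            raise ValueError("binary mask may contain only 0 and 1")
        self.data = self.data.astype(np.uint8)


@dataclass
class ROIAtlas:
    """Integer label volume plus a code -> ROI-name legend.

    Code 0 is reserved for background/undefined (including inter-ROI ties).
    """

    labels: np.ndarray
    legend: dict[int, str]
    voxel_dims: tuple[float, float, float] = (1.0, 1.0, 1.0)
    space_id: str = "MNI"
    orientation: str = "RAS"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("atlas labels must be 3-D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            if not np.array_equal(self.labels, self.labels.astype(int)):
                raise ValueError("atlas labels must be integers")
            self.labels = self.labels.astype(int)
        if 0 in self.legend:
            raise ValueError("legend code 0 is reserved for background")
        used = set(np.unique(self.labels)) - {0}
        unknown = used - set(self.legend)
        if unknown:
            raise ValueError(f"atlas codes missing from legend: {sorted(unknown)}")

    def roi_mask(self, name: str) -> np.ndarray:
        codes = [c for c, n in self.legend.items() if n == name]
        if not codes:
            raise KeyError(f"unknown ROI: {name!r}")
        return np.isin(self.labels, codes)

    @property
    def roi_names(self) -> list[str]:
        return [self.legend[c] for c in sorted(self.legend)]


@dataclass
class DamageProfile:
    """Per-patient damage summary: proportion of each ROI lesioned, and
    total lesion volume.  Empty ROIs are reported as NaN, never 0."""

    patient: str
    damage: dict[str, float]
    lesion_volume_cm3: float
    flags: list[str] = field(default_factory=list)


def _check_same_grid(a, b) -> None:
    sa = a.data.shape if hasattr(a, "data") else a.labels.shape
    sb = b.data.shape if hasattr(b, "data") else b.labels.shape
    if sa != sb:
        raise ValueError(f"grid shape mismatch: {sa} vs {sb}")
    if tuple(a.voxel_dims) != tuple(b.voxel_dims):
        raise ValueError("voxel dimension mismatch")
    if a.space_id != b.space_id:
        raise ValueError(f"space mismatch: {a.space_id} vs {b.space_id}")


def binarize_mask(warped: VolumeGrid, threshold: float = 0.5) -> BinaryMask:
    """Re-binarise an interpolated warped lesion mask.

    A voxel is damaged iff its value is strictly greater than ``threshold``
    (the 0.5 default, with strict inequality, slightly smooths fine
    variations introduced by trilinear interpolation).  Values must lie in
    [0, 1] up to 1e-6.
    """
    lo, hi = warped.data.min(), warped.data.max()
    if lo < -1e-6 or hi > 1 + 1e-6:
        raise ValueError(f"mask values outside [0,1]: range [{lo}, {hi}]")
    return BinaryMask(
        data=(warped.data > threshold).astype(np.uint8),
        voxel_dims=warped.voxel_dims,
        space_id=warped.space_id,
        orientation=warped.orientation,
    )


def build_max_prob_atlas(
    drawings: Mapping[str, Sequence[BinaryMask]],
    tie_code: int = 0,
) -> tuple[dict[str, VolumeGrid], ROIAtlas]:
    """Combine per-rater ROI drawings into probability maps and a
    maximum-probability atlas.

    For each ROI the probability map is the fraction of raters marking each
    voxel.  Each voxel with a positive maximum probability is assigned the
    argmax ROI; voxels where two or more ROIs tie exactly for first place
    are left undefined (``tie_code``, default background).  Legend codes
    follow the input ROI order (1..K); the labelling is order-independent
    except at exact ties, which map to ``tie_code`` regardless of order.
    """
    if not drawings:
        raise ValueError("no ROI drawings supplied")
    names = list(drawings)
    ref = None
    prob = {}
    for name in names:
        masks = list(drawings[name])
        if not masks:
            raise ValueError(f"no rater drawings for ROI {name!r}")
        for m in masks:
            if ref is None:
                ref = m
            else:
                _check_same_grid(ref, m)
        stack = np.stack([m.data for m in masks]).astype(float)
        prob[name] = VolumeGrid(
            data=stack.mean(axis=0),
            voxel_dims=ref.voxel_dims,
            space_id=ref.space_id,
            orientation=ref.orientation,
        )

    pstack = np.stack([prob[n].data for n in names])  # (K, x, y, z)
    pmax = pstack.max(axis=0)
    n_at_max = (pstack == pmax[None]).sum(axis=0)
    argmax = pstack.argmax(axis=0)
    labels = np.where(pmax > 0, argmax + 1, 0)
    labels = np.where((pmax > 0) & (n_at_max > 1), tie_code, labels)
    legend = {i + 1: n for i, n in enumerate(names)}
    atlas = ROIAtlas(
        labels=labels.astype(int),
        legend=legend,
        voxel_dims=ref.voxel_dims,
        space_id=ref.space_id,
        orientation=ref.orientation,
    )
    return prob, atlas


def truncate_posterior(
    atlas: ROIAtlas,
    rois_to_truncate: Sequence[str],
    reference_roi: str,
) -> ROIAtlas:
    """Truncate the listed ROIs posteriorly at the most posterior coronal
    section containing the reference ROI, so they cover the same
    anterior-posterior extent.

    Under the stored orientation (RAS: posterior = decreasing index on the
    anterior-posterior axis), voxels of the listed ROIs strictly posterior
    to the reference's most posterior occupied section become background.
    """
    if atlas.orientation != "RAS":
        raise NotImplementedError(
            f"unsupported orientation record: {atlas.orientation!r}"
        )
    ref = atlas.roi_mask(reference_roi)
    if not ref.any():
        raise ValueError(f"reference ROI {reference_roi!r} is empty")
    y_occupied = np.flatnonzero(ref.any(axis=(0, 2)))
    y_min = y_occupied.min()  # most posterior section containing the reference
    labels = atlas.labels.copy()
    if rois_to_truncate:
        trunc = np.zeros_like(labels, dtype=bool)
        for name in rois_to_truncate:
            trunc |= atlas.roi_mask(name)
        y_index = np.arange(labels.shape[AP_AXIS]).reshape(1, -1, 1)
        posterior = np.broadcast_to(y_index < y_min, labels.shape)
        labels[trunc & posterior] = 0
    return replace(atlas, labels=labels)


def _merge_hemi(name: str) -> str:
    for suffix in ("_L", "_R", "-L", "-R"):
        if name.endswith(suffix):
            return name[: -len(suffix)]
    return name


def roi_damage_profile(
    lesion: BinaryMask,
    atlas: ROIAtlas,
    patient: str = "",
    merge_hemispheres: bool = True,
) -> DamageProfile:
    """Proportion of each ROI damaged, plus total lesion volume in cm^3.

    damage[ROI] is the mean lesion value over the ROI's voxels — the
    proportion of the ROI inside the lesion.  With ``merge_hemispheres``
    (default) left/right ROIs named ``<name>_L``/``<name>_R`` are pooled
    under ``<name>`` before averaging, matching cohorts that pool left- and
    right-lesion patients.  Empty ROIs yield NaN and a flag.
    """
    _check_same_grid(lesion, atlas)
    groups: dict[str, list[int]] = {}
    for code, name in atlas.legend.items():
        key = _merge_hemi(name) if merge_hemispheres else name
        groups.setdefault(key, []).append(code)

    damage, flags = {}, []
    lesion_f = lesion.data.astype(float)
    for name, codes in groups.items():
        m = np.isin(atlas.labels, codes)
        if not m.any():
            damage[name] = float("nan")
            flags.append(f"empty ROI: {name}")
        else:
            damage[name] = float(lesion_f[m].mean())
    volume = float(lesion.data.sum()) * lesion.voxel_volume_mm3 / 1000.0
    return DamageProfile(
        patient=patient, damage=damage, lesion_volume_cm3=volume, flags=flags
    )


def profiles_frame(profiles: Sequence[DamageProfile]) -> pd.DataFrame:
    """Patients x ROI damage proportions (plus lesion volume column)."""
    df = pd.DataFrame([p.damage for p in profiles], index=[p.patient for p in profiles])
    df["lesion_volume_cm3"] = [p.lesion_volume_cm3 for p in profiles]
    df.index.name = "patient"
    return df


def damage_intercorrelations(
    profiles: Sequence[DamageProfile] | pd.DataFrame,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlations between ROIs' damage scores across
    patients.  Returns (r, p, significant) DataFrames; pairs involving a
    zero-variance ROI are NaN (flagged by NaN in ``significant``)."""
    if isinstance(profiles, pd.DataFrame):
        df = profiles.drop(columns=["lesion_volume_cm3"], errors="ignore")
    else:
        df = profiles_frame(profiles).drop(columns="lesion_volume_cm3")
    if len(df) < 3:
        raise ValueError("need at least three patients")
    rois = list(df.columns)
    r = pd.DataFrame(np.eye(len(rois)), index=rois, columns=rois)
    p = pd.DataFrame(np.zeros((len(rois), len(rois))), index=rois, columns=rois)
    for i, a in enumerate(rois):
        for j, b in enumerate(rois):
            if j <= i:
                continue
            x, y = df[a].to_numpy(float), df[b].to_numpy(float)
            ok = ~np.isnan(x) & ~np.isnan(y)
            if ok.sum() < 3 or np.ptp(x[ok]) == 0 or np.ptp(y[ok]) == 0:
                rv, pv = np.nan, np.nan
            else:
                rv, pv = stats.pearsonr(x[ok], y[ok])
            r.loc[a, b] = r.loc[b, a] = rv
            p.loc[a, b] = p.loc[b, a] = pv
    sig = p < alpha
    sig = sig.where(~p.isna())
    return r, p, sig


# ---------------------------------------------------------------------------
# NIfTI I/O (nibabel)
# ---------------------------------------------------------------------------

def _affine(voxel_dims) -> np.ndarray:
    return np.diag(list(voxel_dims) + [1.0])


def write_volume(vol: VolumeGrid | ROIAtlas, path: str) -> None:
    import nibabel as nib

    data = vol.data if isinstance(vol, VolumeGrid) else vol.labels
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), _affine(vol.voxel_dims))
    nib.save(img, path)


def read_volume(path: str, space_id: str = "MNI", binary: bool = False) -> VolumeGrid:
    import nibabel as nib

    img = nib.load(path)
    data = np.asanyarray(img.dataobj, dtype=float)
    dims = tuple(float(z) for z in img.header.get_zooms()[:3])
    cls = BinaryMask if binary else VolumeGrid
    if binary:
        data = np.rint(data)
    return cls(data=data, voxel_dims=dims, space_id=space_id)


def write_atlas(atlas: ROIAtlas, path: str, legend_path: str | None = None) -> None:
    write_volume(atlas, path)
    if legend_path is None:
        legend_path = os.path.splitext(path.removesuffix(".gz"))[0] + "_legend.tsv"
    pd.DataFrame(
        sorted(atlas.legend.items()), columns=["code", "name"]
    ).to_csv(legend_path, sep="\t", index=False)


def read_atlas(path: str, legend_path: str, space_id: str = "MNI") -> ROIAtlas:
    vol = read_volume(path, space_id=space_id)
    legend_df = pd.read_csv(legend_path, sep="\t")
    legend = dict(zip(legend_df["code"].astype(int), legend_df["name"]))
    return ROIAtlas(
        labels=np.rint(vol.data).astype(int),
        legend=legend,
        voxel_dims=vol.voxel_dims,
        space_id=space_id,
    )
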