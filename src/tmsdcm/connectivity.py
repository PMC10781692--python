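"""Seed-based functional connectivity and stimulation-target selection.

Covers the imaging steps between preprocessing and effective-connectivity
modelling: extracting a spherical seed time course at the individualized
DLPFC target, whole-brain Pearson r maps, Fisher z transformation,
group-level signed (positive/negative) connectivity maps via one-sample
t-tests, selection of the stimulation target as the DLPFC location most
anticorrelated with the subgenual cingulate (atlas labels 187+188), ROI
mask construction from signed maps intersected with atlas labels, and mean
time-course extraction.

Volumes are handled as ``(data, affine)`` pairs or nibabel spatial images;
coordinates are MNI mm through the NIfTI affine, voxel indices are
0-based.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "SeedSpec",
    "FCMap",
    "ROIMaskSet",
    "seed_timecourse",
    "fc_map",
    "fisher_z",
    "group_signed_maps",
    "paired_difference_map",
    "select_target",
    "build_roi_masks",
    "extract_roi_series",
    "sphere_mask",
]

# signed-map membership of the network ROIs: which polarity map each ROI is
# required to intersect, and whether it is restricted to the left hemisphere
DEFAULT_LATERALITY_RULES = {
    "CAU": ("positive", True),
    "mPFC": ("positive", False),
    "PCUN": ("negative", True),
    "HIP": ("negative", True),
    "INS": ("negative", True),
    "sgACC": ("negative", False),
}


def _as_data_affine(volume):
    """Accept a nibabel image or a (data, affine) pair."""
    if isinstance(volume, tuple):
        data, affine = volume
        return np.asarray(data), np.asarray(affine, float)
    return np.asanyarray(volume.dataobj), np.asarray(volume.affine, float)


@dataclass
class SeedSpec:
    """Spherical seed in MNI mm."""

    center: tuple[float, float, float]
    radius: float = 6.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("seed radius must be positive")


@dataclass
class FCMap:
    """Per-voxel statistic volume with a kind tag ('r', 'z' or 't')."""

    data: np.ndarray
    kind: str
    affine: np.ndarray
    dof: int | None = None
    undefined: np.ndarray | None = None  # voxels where the statistic was undefined

    def __post_init__(self) -> None:
        if self.kind == "r" and np.nanmax(np.abs(self.data), initial=0.0) > 1 + 1e-12:
            raise ValueError("r values must lie in [-1, 1]")


@dataclass
class ROIMaskSet:
    """Named binary ROI masks sharing one grid."""

    masks: dict[str, np.ndarray]
    affine: np.ndarray
    polarity: dict[str, str] = field(default_factory=dict)
    laterality: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, m in self.masks.items():
            if not m.any():
                raise ValueError(f"ROI mask {name!r} is empty")


def voxel_centers_mm(shape: tuple[int, int, int], affine: np.ndarray) -> np.ndarray:
    """MNI mm coordinates of all voxel centers, shape (nx, ny, nz, 3)."""
    ii, jj, kk = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    vox = np.stack([ii, jj, kk, np.ones_like(ii)], axis=-1)
    return vox @ affine.T[:, :3]


def sphere_mask(shape: tuple[int, int, int], affine: np.ndarray, seed: SeedSpec) -> np.ndarray:
    """Voxels whose center lies within the seed sphere (Euclidean mm)."""
    mm = voxel_centers_mm(shape, affine)
    d2 = np.sum((mm - np.asarray(seed.center)) ** 2, axis=-1)
    return d2 <= seed.radius**2


def seed_timecourse(volume, seed: SeedSpec) -> np.ndarray:
    """Mean series over voxels inside a spherical seed."""
    data, affine = _as_data_affine(volume)
    mask = sphere_mask(data.shape[:3], affine, seed)
    if not mask.any():
        raise ValueError(f"seed sphere at {seed.center} (r={seed.radius} mm) misses the grid")
    return data[mask].mean(axis=0)


def fc_map(seed_series: np.ndarray, volume) -> FCMap:
    """Whole-brain Pearson correlation map against a seed series.

    Constant voxels have undefined r; they are recorded as 0 and flagged in
    ``FCMap.undefined``.
    """
    data, affine = _as_data_affine(volume)
    s = np.asarray(seed_series, float)
    if data.shape[-1] != s.shape[0]:
        raise ValueError("series length does not match volume frames")
    if s.shape[0] < 3:
        raise ValueError("need at least 3 frames")
    s = s - s.mean()
    ss = np.sqrt(np.sum(s**2))
    if ss == 0:
        raise ValueError("seed series is constant")
    x = data - data.mean(axis=-1, keepdims=True)
    denom = np.sqrt(np.sum(x**2, axis=-1)) * ss
    undefined = denom == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(undefined, 0.0, np.tensordot(x, s, axes=([-1], [0])) / np.where(undefined, 1.0, denom))
    r = np.clip(r, -1.0, 1.0)
    return FCMap(r, "r", affine, dof=s.shape[0] - 2, undefined=undefined)


def fisher_z(rmap: FCMap) -> FCMap:
    """Voxelwise Fisher z = atanh(r); |r| clipped at 1 - 1e-7 with a warning."""
    if rmap.kind != "r":
        raise ValueError("fisher_z expects an r map")
    r = rmap.data
    lim = 1.0 - 1e-7
    if np.any(np.abs(r) > lim):
        warnings.warn("|r| values at 1 clipped before Fisher transform", stacklevel=2)
        r = np.clip(r, -lim, lim)
    return FCMap(np.arctanh(r), "z", rmap.affine, dof=rmap.dof, undefined=rmap.undefined)


def group_signed_maps(z_maps: list[FCMap], alpha: float = 0.05):
    """Positive and negative group connectivity maps via one-sample t-tests.

    Voxelwise t of the subjects' z values against zero; the positive mask
    collects voxels with t > 0 and two-sided p < alpha, the negative mask
    t < 0 and p < alpha. Zero-variance voxels are excluded from both masks
    and flagged. Returns ``(t_map, positive_mask, negative_mask)``.
    """
    if len(z_maps) < 3:
        raise ValueError("need at least 3 subjects")
    stack = np.stack([m.data for m in z_maps], axis=0)
    n = stack.shape[0]
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    zero_var = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(zero_var, 0.0, mean / np.where(zero_var, 1.0, sd / np.sqrt(n)))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    sig = (p < alpha) & ~zero_var
    # zero-variance voxels with nonzero mean are t -> inf: include by limit
    inf_pos = zero_var & (mean > 0)
    inf_neg = zero_var & (mean < 0)
    positive = (sig & (t > 0)) | inf_pos
    negative = (sig & (t < 0)) | inf_neg
    tmap = FCMap(t, "t", z_maps[0].affine, dof=n - 1, undefined=zero_var & (mean == 0))
    return tmap, positive, negative


def paired_difference_map(pre_maps: list[FCMap], post_maps: list[FCMap], alpha: float = 0.05):
    """Paired-t pre-vs-post map with Benjamini–Hochberg FDR control.

    Returns ``(t_map, significant_mask)``; used to test whether the
    target-based connectivity profile changed between sessions.
    """
    if len(pre_maps) != len(post_maps):
        raise ValueError("pre and post lists must align")
    pre = np.stack([m.data for m in pre_maps], axis=0)
    post = np.stack([m.data for m in post_maps], axis=0)
    d = post - pre
    n = d.shape[0]
    sd = d.std(axis=0, ddof=1)
    zero = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(zero, 0.0, d.mean(axis=0) / np.where(zero, 1.0, sd / np.sqrt(n)))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    flat = p.ravel()
    reject = np.zeros(flat.shape, bool)
    order = np.argsort(flat)
    m = flat.size
    thresh = alpha * (np.arange(1, m + 1)) / m
    passed = flat[order] <= thresh
    if passed.any():
        kmax = np.max(np.nonzero(passed)[0])
        reject[order[: kmax + 1]] = True
    return FCMap(t, "t", pre_maps[0].affine, dof=n - 1), reject.reshape(p.shape)


def select_target(
    volume,
    dlpfc_mask: np.ndarray,
    atlas,
    sgacc_labels: tuple[int, ...] = (187, 188),
) -> tuple[tuple[float, float, float], float]:
    """Individualized stimulation target: DLPFC voxel most anticorrelated
    with the subgenual cingulate reference series.

    The sgACC reference is the mean series over the union of the given
    atlas labels. Returns the MNI mm coordinate of the minimum-correlation
    voxel inside the DLPFC mask and its r value; ties break at the smallest
    flat voxel index. If no voxel is negatively correlated the minimum is
    still returned, with a warning.
    """
    data, affine = _as_data_affine(volume)
    labels, la = _as_data_affine(atlas)
    if labels.shape != data.shape[:3]:
        raise ValueError("atlas grid does not match volume")
    if not dlpfc_mask.any():
        raise ValueError("empty DLPFC mask")
    ref_mask = np.isin(labels, list(sgacc_labels))
    if not ref_mask.any():
        raise ValueError(f"atlas contains none of the sgACC labels {sgacc_labels}")
    ref = data[ref_mask].mean(axis=0)
    rmap = fc_map(ref, (data, affine))
    r_in = np.where(dlpfc_mask, rmap.data, np.inf)
    flat_idx = int(np.argmin(r_in.ravel()))  # argmin takes the first (smallest) index on ties
    r_val = float(r_in.ravel()[flat_idx])
    if r_val >= 0:
        warnings.warn("no negatively correlated voxel in DLPFC mask; returning minimum", stacklevel=2)
    ijk = np.unravel_index(flat_idx, data.shape[:3])
    mm = affine @ np.array([*ijk, 1.0])
    return tuple(float(v) for v in mm[:3]), r_val


def build_roi_masks(
    positive_mask: np.ndarray,
    negative_mask: np.ndarray,
    atlas,
    label_map: dict[str, list[int]],
    laterality_rules: dict[str, tuple[str, bool]] | None = None,
    fallback_to_atlas: bool = False,
) -> ROIMaskSet:
    """ROI masks = atlas labels intersected with the matching signed map.

    ``laterality_rules`` maps ROI name -> (polarity, left_only); lateral
    ROIs are restricted to the left hemisphere (voxel centers with
    MNI x < 0), midline ROIs keep both hemispheres. An empty intersection
    for a required ROI raises an error naming it, unless
    ``fallback_to_atlas`` is set, in which case the full (laterality-
    restricted) anatomical label is used with a warning.
    """
    labels, affine = _as_data_affine(atlas)
    rules = laterality_rules if laterality_rules is not None else DEFAULT_LATERALITY_RULES
    x_mm = voxel_centers_mm(labels.shape, affine)[..., 0]
    masks, polarity, laterality = {}, {}, {}
    for name, (pol, left_only) in rules.items():
        if name not in label_map:
            continue
        lab_mask = np.isin(labels, label_map[name])
        signed = positive_mask if pol == "positive" else negative_mask
        m = lab_mask & signed
        if left_only:
            m = m & (x_mm < 0)
        if not m.any():
            if not fallback_to_atlas:
                raise ValueError(f"ROI {name!r}: empty intersection of atlas labels and {pol} map")
            warnings.warn(f"ROI {name!r}: signed map missed the label; using the atlas label",
                          stacklevel=2)
            m = lab_mask & (x_mm < 0) if left_only else lab_mask
        masks[name] = m
        polarity[name] = pol
        laterality[name] = "left" if left_only else "bilateral"
    return ROIMaskSet(masks, affine, polarity, laterality)


def extract_roi_series(volume, mask: np.ndarray) -> np.ndarray:
    """Arithmetic mean over mask voxels, per frame."""
    data, _ = _as_data_affine(volume)
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("empty ROI mask")
    return data[mask].mean(axis=0)
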