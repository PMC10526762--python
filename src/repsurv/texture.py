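"""Conventional 3D radiomics: quantization, texture matrices, histogram,
shape, and volumetric features.

Three texture matrices are implemented, each over a quantized region:

* GTSDM (gray-tone spatial dependence / co-occurrence): counts of level
  pairs at a voxel offset, accumulated symmetrically over 13 unique 3D
  directions at a configurable distance.
* NGTDM (neighborhood gray-tone difference): per-level summed absolute
  deviation from the 26-neighborhood mean, with the Amadasun-King
  coarseness/contrast/busyness/complexity/strength statistics.
* GLZSM (gray-level size-zone): counts of 26-connected zones by level and
  size, with the standard size-zone emphasis statistics.

Feature names follow the legacy conventions used in published glioma
radiomics feature lists (mixed CamelCase / underscore styles, e.g.
``LargeZoneLowGrayEmphasis`` next to ``Low_Gray_Level_Zone_Emphasis``);
the naming is deliberately kept verbatim so selected-feature lists from
such reports resolve against tables produced here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

log = logging.getLogger(__name__)

__all__ = [
    "QuantizedRegion",
    "quantize_region",
    "gtsdm_features",
    "ngtdm_features",
    "glzsm_features",
    "histogram_stats",
    "shape_features",
    "volumetric_features",
    "extract_all_features",
    "LabeledStudy",
    "FeatureConfig",
    "feature_names",
    "UNIQUE_DIRECTIONS_3D",
]

_EPS = 1e-12

# 13 unique 3D offsets (half of the 26-neighborhood; the other half is
# covered by symmetric accumulation)
UNIQUE_DIRECTIONS_3D = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
)


# ----------------------------------------------------------------------
# quantization
# ----------------------------------------------------------------------

@dataclass
class QuantizedRegion:
    """Equal-width quantization of a masked region onto levels 1..n_levels.

    ``levels`` is 0 outside the mask; the in-mask min..max of the source
    intensities maps onto 1..n_levels (a constant region maps to level 1).
    """

    levels: np.ndarray
    mask: np.ndarray
    n_levels: int
    spacing: tuple = (1.0, 1.0, 1.0)


def quantize_region(intensity: np.ndarray, mask: np.ndarray, n_levels: int = 32,
                    spacing=(1.0, 1.0, 1.0)) -> QuantizedRegion:
    """Equal-width binning of in-mask intensities into ``n_levels`` levels."""
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < 2:
        raise ValueError("quantize_region needs a mask with at least 2 voxels")
    if n_levels < 2:
        raise ValueError("need at least 2 gray levels")
    vals = np.asarray(intensity, dtype=float)
    lo = vals[mask].min()
    hi = vals[mask].max()
    levels = np.zeros(vals.shape, dtype=np.int32)
    if hi > lo:
        lv = np.floor((vals[mask] - lo) / (hi - lo) * n_levels).astype(np.int32) + 1
        levels[mask] = np.clip(lv, 1, n_levels)
    else:
        levels[mask] = 1
    return QuantizedRegion(levels=levels, mask=mask, n_levels=n_levels, spacing=tuple(spacing))


# ----------------------------------------------------------------------
# GTSDM (co-occurrence)
# ----------------------------------------------------------------------

def _cooccurrence_matrix(levels: np.ndarray, mask: np.ndarray, n_levels: int,
                         offset: tuple[int, int, int]) -> np.ndarray:
    """Symmetric normalized co-occurrence matrix for one offset, or None."""
    sl_a, sl_b = [], []
    for o in offset:
        if o >= 0:
            sl_a.append(slice(None, levels.shape[len(sl_a)] - o or None))
            sl_b.append(slice(o, None))
        else:
            sl_a.append(slice(-o, None))
            sl_b.append(slice(None, o))
    a = levels[tuple(sl_a)]
    b = levels[tuple(sl_b)]
    valid = (a > 0) & (b > 0)
    if not valid.any():
        return None
    pairs = np.ravel_multi_index((a[valid] - 1, b[valid] - 1), (n_levels, n_levels))
    m = np.bincount(pairs, minlength=n_levels * n_levels).reshape(n_levels, n_levels).astype(float)
    m = m + m.T  # symmetric accumulation
    return m / m.sum()


def _gtsdm_stats(p: np.ndarray) -> dict:
    ng = p.shape[0]
    i = np.arange(1, ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    mu = (i * px).sum()
    sigma2 = ((i - mu) ** 2 * px).sum()
    out = {
        "Autocorrelation": float((ii * jj * p).sum()),
        "Contrast": float(((ii - jj) ** 2 * p).sum()),
        "Dissimilarity": float((np.abs(ii - jj) * p).sum()),
        "Energy": float((p ** 2).sum()),
        "Entropy": float(-(p[p > 0] * np.log2(p[p > 0])).sum()),
        "Homogeneity": float((p / (1.0 + (ii - jj) ** 2)).sum()),
        "MaximumProbability": float(p.max()),
        "SumAverage": float(((ii + jj) * p).sum()),
        "Variance": float(sigma2),
        "ClusterShade": float(((ii + jj - 2 * mu) ** 3 * p).sum()),
        "ClusterProminence": float(((ii + jj - 2 * mu) ** 4 * p).sum()),
    }
    if sigma2 > _EPS:
        out["Correlation"] = float(((ii - mu) * (jj - mu) * p).sum() / sigma2)
    else:
        out["Correlation"] = 1.0  # degenerate single-level region
    return out


GTSDM_STATS = tuple(_gtsdm_stats(np.ones((2, 2)) / 4.0).keys())


def gtsdm_features(q: QuantizedRegion, distance: int = 1,
                   directions=None, per_direction: bool = False) -> dict:
    """Co-occurrence statistics, direction-averaged (and per-direction).

    Directions with no valid in-mask voxel pair are skipped; if no
    direction has a pair the features are returned as NaN and logged.
    """
    if directions is None:
        directions = UNIQUE_DIRECTIONS_3D if q.levels.ndim == 3 else ((0, 1), (1, 0), (1, 1), (1, -1))
    per_dir = []
    feats = {}
    for d_idx, direction in enumerate(directions):
        offset = tuple(int(distance) * np.asarray(direction))
        m = _cooccurrence_matrix(q.levels, q.mask, q.n_levels, tuple(offset))
        if m is None:
            log.warning("GTSDM: no valid pairs for offset %s; direction skipped", offset)
            continue
        s = _gtsdm_stats(m)
        per_dir.append(s)
        if per_direction:
            for k, v in s.items():
                feats[f"GTSDM_d{d_idx + 1}_{k}"] = v
    if not per_dir:
        log.warning("GTSDM: no valid pairs in any direction; features missing")
        for k in GTSDM_STATS:
            feats[f"GTSDM_{k}"] = float("nan")
        return feats
    for k in per_dir[0]:
        feats[f"GTSDM_{k}"] = float(np.mean([s[k] for s in per_dir]))
    return feats


# ----------------------------------------------------------------------
# NGTDM
# ----------------------------------------------------------------------

def ngtdm_features(q: QuantizedRegion) -> dict:
    """Amadasun-King neighborhood gray-tone difference statistics.

    The neighborhood is the full 26-neighborhood (8 in 2D) restricted to
    in-mask voxels; voxels with no in-mask neighbor are excluded.
    """
    if q.mask.sum() < 2:
        raise ValueError("NGTDM needs a region with at least one neighborhood")
    kernel = np.ones((3,) * q.levels.ndim)
    kernel[(1,) * q.levels.ndim] = 0
    lv = q.levels.astype(float) * q.mask
    nbr_sum = ndimage.convolve(lv, kernel, mode="constant", cval=0.0)
    nbr_cnt = ndimage.convolve(q.mask.astype(float), kernel, mode="constant", cval=0.0)
    valid = q.mask & (nbr_cnt > 0)
    if not valid.any():
        raise ValueError("NGTDM: no voxel has an in-mask neighbor")
    diff = np.abs(q.levels[valid] - nbr_sum[valid] / nbr_cnt[valid])
    lab = q.levels[valid]

    n_v = valid.sum()
    s_i = np.bincount(lab, weights=diff, minlength=q.n_levels + 1)[1:]
    n_i = np.bincount(lab, minlength=q.n_levels + 1)[1:]
    p_i = n_i / n_v
    occ = p_i > 0
    levels_occ = np.arange(1, q.n_levels + 1)[occ]
    p, s = p_i[occ], s_i[occ]
    ngp = occ.sum()

    ii, jj = np.meshgrid(levels_occ, levels_occ, indexing="ij")
    pi, pj = np.meshgrid(p, p, indexing="ij")
    si, sj = np.meshgrid(s, s, indexing="ij")

    coarseness = 1.0 / (_EPS + (p * s).sum())
    if ngp > 1:
        contrast = ((pi * pj * (ii - jj) ** 2).sum() / (ngp * (ngp - 1))) * (s.sum() / n_v)
    else:
        contrast = 0.0
    denom = np.abs(np.subtract.outer(levels_occ * p, levels_occ * p)).sum()
    busyness = (p * s).sum() / denom if denom > _EPS else 0.0
    complexity = (np.abs(ii - jj) * (pi * si + pj * sj) / (pi + pj)).sum() / n_v
    strength = ((pi + pj) * (ii - jj) ** 2).sum() / (_EPS + s.sum())
    return {
        "NGTDM_Coarseness": float(coarseness),
        "NGTDM_Contrast": float(contrast),
        "NGTDM_Busyness": float(busyness),
        "NGTDM_Complexity": float(complexity),
        "NGTDM_Strength": float(strength),
    }


NGTDM_STATS = ("Coarseness", "Contrast", "Busyness", "Complexity", "Strength")


# ----------------------------------------------------------------------
# GLZSM
# ----------------------------------------------------------------------

def glzsm_features(q: QuantizedRegion, connectivity: int | None = None) -> dict:
    """Size-zone statistics from 26-connected (default) same-level zones."""
    if not q.mask.any():
        raise ValueError("GLZSM needs a non-empty mask")
    ndim = q.levels.ndim
    if connectivity is None:
        connectivity = ndim  # full (26 in 3D) connectivity
    structure = ndimage.generate_binary_structure(ndim, connectivity)
    zones = {}  # (level, size) -> count
    max_size = 0
    for level in range(1, q.n_levels + 1):
        binary = q.levels == level
        if not binary.any():
            continue
        lab, n_zones = ndimage.label(binary, structure=structure)
        sizes = np.bincount(lab.ravel())[1:]
        for sz in sizes:
            zones[(level, int(sz))] = zones.get((level, int(sz)), 0) + 1
            max_size = max(max_size, int(sz))
    n_z = sum(zones.values())
    n_vox = int(q.mask.sum())

    iv = np.array([k[0] for k in zones], dtype=float)
    jv = np.array([k[1] for k in zones], dtype=float)
    cnt = np.array(list(zones.values()), dtype=float)
    pz = cnt / n_z

    gl_counts = pd.Series(cnt).groupby(iv).sum().to_numpy()
    sz_counts = pd.Series(cnt).groupby(jv).sum().to_numpy()
    mu_i = (pz * iv).sum()
    mu_j = (pz * jv).sum()
    feats = {
        "SmallZoneEmphasis": float((pz / jv ** 2).sum()),
        "LargeZoneEmphasis": float((pz * jv ** 2).sum()),
        "Low_Gray_Level_Zone_Emphasis": float((pz / iv ** 2).sum()),
        "High_Gray_Level_Zone_Emphasis": float((pz * iv ** 2).sum()),
        "SmallZoneLowGrayEmphasis": float((pz / (iv ** 2 * jv ** 2)).sum()),
        "SmallZoneHighGrayEmphasis": float((pz * iv ** 2 / jv ** 2).sum()),
        "LargeZoneLowGrayEmphasis": float((pz * jv ** 2 / iv ** 2).sum()),
        "LargeZoneHighGrayEmphasis": float((pz * iv ** 2 * jv ** 2).sum()),
        "GrayLevelNonUniformity": float((gl_counts ** 2).sum() / n_z),
        "ZoneSizeNonUniformity": float((sz_counts ** 2).sum() / n_z),
        "ZonePercentage": float(n_z / n_vox),
        "GrayLevelVariance": float((pz * (iv - mu_i) ** 2).sum()),
        "ZoneSizeVariance": float((pz * (jv - mu_j) ** 2).sum()),
    }
    return {f"GLZSM_{k}": v for k, v in feats.items()}


GLZSM_STATS = (
    "SmallZoneEmphasis", "LargeZoneEmphasis", "Low_Gray_Level_Zone_Emphasis",
    "High_Gray_Level_Zone_Emphasis", "SmallZoneLowGrayEmphasis",
    "SmallZoneHighGrayEmphasis", "LargeZoneLowGrayEmphasis",
    "LargeZoneHighGrayEmphasis", "GrayLevelNonUniformity",
    "ZoneSizeNonUniformity", "ZonePercentage", "GrayLevelVariance",
    "ZoneSizeVariance",
)


# ----------------------------------------------------------------------
# histogram statistics
# ----------------------------------------------------------------------

def histogram_stats(intensity: np.ndarray, mask: np.ndarray, bins: int = 64) -> dict:
    """Mean, variance, skewness, kurtosis, energy and entropy of the region.

    Energy and entropy are computed on a normalized fixed-bin histogram of
    the in-mask range (base-2 log). A constant region has undefined
    skewness/kurtosis, flagged as zero and logged.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < 2:
        raise ValueError("histogram_stats needs at least 2 in-mask voxels")
    v = np.asarray(intensity, dtype=float)[mask]
    var = float(v.var(ddof=1))
    if var > 0:
        skew = float(stats.skew(v))
        kurt = float(stats.kurtosis(v, fisher=False))
    else:
        log.warning("histogram_stats: constant region; skewness/kurtosis set to 0")
        skew = kurt = 0.0
    if v.max() > v.min():
        hist, _ = np.histogram(v, bins=bins, range=(v.min(), v.max()))
    else:
        hist = np.array([v.size])
    p = hist / hist.sum()
    p_nz = p[p > 0]
    return {
        "Histogram_Mean": float(v.mean()),
        "Histogram_Variance": var,
        "Histogram_Skewness": skew,
        "Histogram_Kurtosis": kurt,
        "Histogram_Energy": float((p ** 2).sum()),
        "Histogram_Entropy": float(-(p_nz * np.log2(p_nz)).sum()),
    }


# ----------------------------------------------------------------------
# shape and volume
# ----------------------------------------------------------------------

def shape_features(mask: np.ndarray, spacing=(1.0, 1.0, 1.0)) -> dict:
    """Principal-axis shape descriptors of a voxel mask, spacing-scaled.

    Axis lengths use the 4*sqrt(eigenvalue) moment convention; the
    orientation of each principal axis is its angle (degrees) to the
    corresponding image axis; eccentricity is sqrt(1 - lambda2/lambda1);
    extent is mask volume over bounding-box volume.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < 10:
        raise ValueError("shape_features needs a mask with >= 10 voxels")
    coords = np.argwhere(mask).astype(float) * np.asarray(spacing, float)
    cov = np.cov(coords, rowvar=False, bias=True)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    if evals[2] <= _EPS:
        log.warning("shape_features: degenerate (coplanar) mask; third axis length 0")
    lengths = 4.0 * np.sqrt(evals)
    # angle between axis k's eigenvector and image axis k, in degrees
    orient = [float(np.degrees(np.arccos(np.clip(abs(evecs[k, k]), 0.0, 1.0))))
              for k in range(3)]
    ecc = float(np.sqrt(1.0 - evals[1] / evals[0])) if evals[0] > _EPS else 0.0
    mins = coords.min(axis=0)
    maxs = coords.max(axis=0)
    sp = np.asarray(spacing, float)
    bbox_vol = np.prod(maxs - mins + sp)  # voxel-closed bounding box
    extent = float(mask.sum() * np.prod(sp) / bbox_vol)
    return {
        "FirstAxisLength": float(lengths[0]),
        "SecondAxisLength": float(lengths[1]),
        "ThirdAxisLength": float(lengths[2]),
        "Orientation_1": orient[0],
        "Orientation_2": orient[1],
        "Orientation_3": orient[2],
        "Eccentricity": ecc,
        "Extent": extent,
        "up_left_x": float(mins[0]),
        "up_left_y": float(mins[1]),
        "up_left_z": float(mins[2]),
    }


def volumetric_features(labels: np.ndarray, brain_mask: np.ndarray,
                        spacing=(1.0, 1.0, 1.0)) -> dict:
    """Volumes (mm^3) of whole tumor and sub-regions, and tumor/brain ratio."""
    labels = np.asarray(labels)
    allowed = {0, 1, 2, 4}
    present = set(np.unique(labels).tolist())
    if not present <= allowed:
        raise ValueError(f"label codes must be within {sorted(allowed)}, got {sorted(present)}")
    brain_mask = np.asarray(brain_mask, dtype=bool)
    tumor = labels > 0
    if np.any(tumor & ~brain_mask):
        raise ValueError("tumor voxels outside the brain mask (registration fault?)")
    voxel = float(np.prod(spacing))
    vols = {
        "wt_Volume": float(tumor.sum() * voxel),
        "nec_Volume": float((labels == 1).sum() * voxel),
        "edema_Volume": float((labels == 2).sum() * voxel),
        "et_Volume": float((labels == 4).sum() * voxel),
        "brain_Volume": float(brain_mask.sum() * voxel),
    }
    vols["wt_brain_VolumeRatio"] = vols["wt_Volume"] / vols["brain_Volume"]
    return vols


# ----------------------------------------------------------------------
# full per-subject extraction
# ----------------------------------------------------------------------

@dataclass
class LabeledStudy:
    """One subject: co-registered intensity volume + label mask + spacing."""

    intensity: np.ndarray
    labels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    subject_id: str = ""
    brain_mask: np.ndarray | None = None

    def __post_init__(self):
        if self.intensity.shape != self.labels.shape:
            raise ValueError("intensity and labels must share a shape")


# region name -> (label predicate code, name used in matrix/histogram features)
REGIONS = {
    "wt": None,       # whole tumor: labels > 0 (no tag in matrix feature names)
    "edema": 2,
    "et": 4,
    "nec": 1,
}
_REGION_TAG = {"wt": "", "edema": "ED", "et": "ET", "nec": "NEC"}

# legacy per-region shape feature names (kept verbatim so published
# selected-feature lists resolve)
_SHAPE_NAMES = {
    "wt": {
        "FirstAxisLength": "wt_MajorAxisLength",
        "SecondAxisLength": "wt_SecondAxisLength",
        "ThirdAxisLength": "wt_ThirdAxisLength",
        "Orientation_1": "L1_Orientation",
        "Orientation_2": "L2_Orientation",
        "Orientation_3": "L3_Orientation",
        "Eccentricity": "ET2",
        "Extent": "L1_Extent",
        "up_left_x": "WT_up_left_x",
        "up_left_y": "WT_up_left_y",
        "up_left_z": "WT_up_left_z",
    },
    "edema": {
        "FirstAxisLength": "edema_FirstAxisLength",
        "SecondAxisLength": "edema_SecondAxisLength",
        "ThirdAxisLength": "edema_ThirdAxisLength",
        "Orientation_1": "edema_Orientation_1",
        "Orientation_2": "edema_Orientation_2",
        "Orientation_3": "edema_Orientation_3",
        "Eccentricity": "edema_Eccentricity",
        "Extent": "edema_Extent",
        "up_left_x": "ED_up_left_x",
        "up_left_y": "ED_up_left_y",
        "up_left_z": "ED_up_left_z",
    },
    "et": {
        "FirstAxisLength": "et_FirstAxisLength",
        "SecondAxisLength": "et_SecondAxisLength",
        "ThirdAxisLength": "et_ThirdAxisLength",
        "Orientation_1": "et_Orientation_1",
        "Orientation_2": "et_Orientation_2",
        "Orientation_3": "et_Orientation_3",
        "Eccentricity": "et_Eccentricity",
        "Extent": "et_Extent",
        "up_left_x": "ET_up_left_x",
        "up_left_y": "ET_up_left_y",
        "up_left_z": "ET_up_left_z",
    },
    "nec": {
        "FirstAxisLength": "nec_FirstAxisLength",
        "SecondAxisLength": "nec_SecondAxis_1",
        "ThirdAxisLength": "nec_ThirdAxisLength",
        "Orientation_1": "nec_Orientation_1",
        "Orientation_2": "nec_Orientation_2",
        "Orientation_3": "nec_Orientation_3",
        "Eccentricity": "nec_Eccentricity",
        "Extent": "nec_Extent",
        "up_left_x": "NEC_up_left_x",
        "up_left_y": "NEC_up_left_y",
        "up_left_z": "NEC_up_left_z",
    },
}

_HIST_STATS = ("Mean", "Variance", "Skewness", "Kurtosis", "Energy", "Entropy")
_VOL_NAMES = ("wt_Volume", "nec_Volume", "edema_Volume", "et_Volume",
              "brain_Volume", "wt_brain_VolumeRatio")


@dataclass
class FeatureConfig:
    """Parameters and layout of the per-subject feature vector.

    ``sources`` lists the intensity sources fed to the texture matrices:
    the raw T1C volume plus the fractal transform maps (tags as they
    appear in feature names). The full feature list — count and order —
    is a pure function of this config (see :func:`feature_names`).
    """

    n_levels: int = 32
    gtsdm_distance: int = 1
    per_direction: bool = False
    histogram_bins: int = 64
    regions: tuple = ("wt", "edema", "et", "nec")
    sources: tuple = ("", "ptpsa", "mBm", "GmBm")   # "" = raw intensity
    # fractal map parameters (see repsurv.fractal)
    ptpsa_window: int = 8
    ptpsa_scales: tuple = (2, 4, 8)
    holder_lags: tuple = (1, 2, 4)
    gmbm_lags: tuple = (2, 4, 8)
    holder_radius: int = 4
    min_region_voxels: int = 12

    @property
    def n_features(self) -> int:
        return len(feature_names(self))


def _matrix_stat_names(cfg: FeatureConfig, source: str, region: str) -> list[str]:
    tag = _REGION_TAG[region]
    parts = [p for p in ("T1C", tag, source) if p]
    prefix = "_".join(parts)
    names = [f"{prefix}_GTSDM_{s}" for s in GTSDM_STATS]
    if cfg.per_direction:
        n_dir = len(UNIQUE_DIRECTIONS_3D)
        names += [f"{prefix}_GTSDM_d{d}_{s}" for d in range(1, n_dir + 1) for s in GTSDM_STATS]
    names += [f"{prefix}_NGTDM_{s}" for s in NGTDM_STATS]
    names += [f"{prefix}_GLZSM_{s}" for s in GLZSM_STATS]
    return names


def feature_names(cfg: FeatureConfig) -> list[str]:
    """The full, stable, config-determined feature name list."""
    names: list[str] = []
    for region in cfg.regions:
        for source in cfg.sources:
            names += _matrix_stat_names(cfg, source, region)
    for region in cfg.regions:
        tag = _REGION_TAG[region] or "WT"
        names += [f"T1C_{tag}_Histogram_{s}" for s in _HIST_STATS]
    for region in cfg.regions:
        names += list(_SHAPE_NAMES[region].values())
    names += list(_VOL_NAMES)
    assert len(names) == len(set(names)), "feature names must be unique"
    return names


def _region_mask(labels: np.ndarray, region: str) -> np.ndarray:
    code = REGIONS[region]
    return labels > 0 if code is None else labels == code


def extract_all_features(study: LabeledStudy, config: FeatureConfig | None = None) -> pd.Series:
    """Assemble the full named feature vector for one subject.

    Texture matrices are run per (region x source) where the sources are
    the raw intensities and the fractal transform maps; histogram, shape
    and volumetric features are computed per region from the raw volume.
    Any per-feature failure is recorded as NaN with a log entry; the row
    is still produced.
    """
    from . import fractal  # local import to avoid a cycle

    cfg = config or FeatureConfig()
    names = feature_names(cfg)
    row: dict[str, float] = {}

    whole = study.labels > 0
    maps: dict[str, np.ndarray] = {"": study.intensity}
    for source in cfg.sources:
        if source == "":
            continue
        try:
            if source == "ptpsa":
                fm = fractal.ptpsa_map(study.intensity, whole, window=cfg.ptpsa_window,
                                       scales=cfg.ptpsa_scales)
            elif source == "mBm":
                fm = fractal.mbm_holder_map(study.intensity, whole, lags=cfg.holder_lags,
                                            radius=cfg.holder_radius)
            elif source == "GmBm":
                fm = fractal.gmbm_holder_map(study.intensity, whole, lags=cfg.gmbm_lags)
            else:
                raise ValueError(f"unknown source {source!r}")
            maps[source] = fm.values
        except Exception:
            log.exception("fractal map %s failed for subject %s", source, study.subject_id)
            maps[source] = None

    for region in cfg.regions:
        mask = _region_mask(study.labels, region)
        for source in cfg.sources:
            stat_names = _matrix_stat_names(cfg, source, region)
            prefix = stat_names[0].rsplit("GTSDM_", 1)[0]
            vol = maps.get(source)
            if vol is None or mask.sum() < cfg.min_region_voxels:
                if mask.sum() < cfg.min_region_voxels:
                    log.warning("region %s too small (%d voxels) for subject %s; "
                                "texture features missing", region, mask.sum(), study.subject_id)
                continue
            use_mask = mask & np.isfinite(vol)
            if use_mask.sum() < cfg.min_region_voxels:
                log.warning("region %s has too few finite voxels in source %r", region, source)
                continue
            try:
                q = quantize_region(vol, use_mask, cfg.n_levels, study.spacing)
                row.update({prefix + k: v for k, v in
                            gtsdm_features(q, cfg.gtsdm_distance,
                                           per_direction=cfg.per_direction).items()})
                row.update({prefix + k: v for k, v in ngtdm_features(q).items()})
                row.update({prefix + k: v for k, v in glzsm_features(q).items()})
            except Exception:
                log.exception("texture failure region=%s source=%r subject=%s",
                              region, source, study.subject_id)

    for region in cfg.regions:
        mask = _region_mask(study.labels, region)
        tag = _REGION_TAG[region] or "WT"
        if mask.sum() >= 2:
            try:
                h = histogram_stats(study.intensity, mask, cfg.histogram_bins)
                row.update({f"T1C_{tag}_{k}": v for k, v in h.items()})
            except Exception:
                log.exception("histogram failure region=%s subject=%s", region, study.subject_id)
        try:
            sh = shape_features(mask, study.spacing)
            row.update({_SHAPE_NAMES[region][k]: v for k, v in sh.items()})
        except Exception:
            log.warning("shape features unavailable for region %s of subject %s",
                        region, study.subject_id)

    brain = study.brain_mask if study.brain_mask is not None else np.ones_like(whole, bool)
    try:
        row.update(volumetric_features(study.labels, brain, study.spacing))
    except Exception:
        log.exception("volumetric failure subject=%s", study.subject_id)

    out = pd.Series({n: row.get(n, np.nan) for n in names}, name=study.subject_id or None)
    return out
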