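"""Multi-resolution fractal texture maps.

Three voxel-wise transforms characterize local roughness of the T1C
intensity surface:

* PTPSA — piecewise triangular prism surface area. On a 2D axial window
  around each voxel the intensity surface is tiled with cells of growing
  size s; each cell contributes the area of the four triangles spanned by
  its corner intensities and their mean as apex. The log-log slope of the
  total area A(s) against s gives a local fractal dimension FD = 2 - slope,
  clamped to [2, 3]. A flat surface has FD = 2; a fractional Brownian
  surface with Hurst exponent H has FD ~= 3 - H.
* mBm — multifractional Brownian motion Hölder map. The local mean squared
  increment E|I(x+h) - I(x)|^2 over all axis directions is regressed on
  the lag h in log-log coordinates; H(x) = slope / 2, clamped to [0, 1].
* GmBm — generalized (oscillation-based) Hölder map. The local oscillation
  max - min over Chebyshev balls of radius h replaces the second moment;
  H(x) = slope of log-oscillation against log h, clamped to [0, 1].

Both Hölder estimators are slope-based and therefore invariant to affine
intensity transforms a*I + b with a > 0. PTPSA mixes spatial and intensity
units, so intensities are first rescaled to a fixed lag-1 increment scale
(making the map intensity-scale invariant as well); a constant image is
left untouched and maps to FD = 2 exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

log = logging.getLogger(__name__)

__all__ = ["FractalMap", "ptpsa_map", "mbm_holder_map", "gmbm_holder_map",
           "fractal_texture_features"]


@dataclass
class FractalMap:
    """A voxel-wise fractal dimension or Hölder exponent map.

    Values are NaN outside the mask; inside, PTPSA maps live in [2, 3]
    and Hölder maps in [0, 1] after clamping.
    """

    values: np.ndarray
    kind: str                   # one of {"ptpsa", "mbm", "gmbm"}
    scales: tuple
    window: int


def _loglog_slope(ys: list[np.ndarray], xs: np.ndarray) -> np.ndarray:
    """Per-voxel least-squares slope of log(ys) against log(xs)."""
    lx = np.log(np.asarray(xs, float))
    lx = lx - lx.mean()
    denom = (lx ** 2).sum()
    slope = np.zeros_like(ys[0])
    ly = [np.log(np.maximum(y, 1e-300)) for y in ys]
    ly_mean = sum(ly) / len(ly)
    for k, l in enumerate(ly):
        slope += lx[k] * (l - ly_mean)
    return slope / denom


# ----------------------------------------------------------------------
# PTPSA
# ----------------------------------------------------------------------

def _prism_area_grid(img: np.ndarray, s: int) -> np.ndarray:
    """Per-top-left-corner triangular prism surface area at cell size s."""
    a = img[:-s, :-s]
    b = img[s:, :-s]
    c = img[:-s, s:]
    d = img[s:, s:]
    e = (a + b + c + d) / 4.0
    h = s / 2.0

    def tri(z1, z2, ze, p1, p2):
        # corners p1, p2 in the cell plane, apex at the cell center
        v1 = np.array([p2[0] - p1[0], p2[1] - p1[1]])
        v2 = np.array([h - p1[0], h - p1[1]])
        dz1 = z2 - z1
        dz2 = ze - z1
        # |cross((v1, dz1), (v2, dz2))| / 2
        cx = v1[1] * dz2 - dz1 * v2[1]
        cy = dz1 * v2[0] - v1[0] * dz2
        cz = v1[0] * v2[1] - v1[1] * v2[0]
        return 0.5 * np.sqrt(cx ** 2 + cy ** 2 + cz ** 2)

    area = (tri(a, b, e, (0.0, 0.0), (s, 0.0))
            + tri(b, d, e, (s, 0.0), (s, float(s)))
            + tri(d, c, e, (s, float(s)), (0.0, float(s)))
            + tri(c, a, e, (0.0, float(s)), (0.0, 0.0)))
    return area


def ptpsa_map(intensity: np.ndarray, mask: np.ndarray, window: int = 8,
              scales: tuple = (2, 4, 8), gain: float = 24.0) -> FractalMap:
    """Piecewise triangular prism surface area fractal dimension map.

    ``window`` is the radius (voxels) of the axial 2D estimation window;
    ``scales`` the prism cell sizes; ``gain`` the target standard
    deviation of lag-1 intensity increments after internal rescaling
    (vertical relief must dominate the cell size for the area-scaling
    regime to be visible). Windows at the volume edge shrink to fit.
    """
    scales = tuple(int(s) for s in scales)
    if len(scales) < 3:
        raise ValueError("need at least 3 cell sizes")
    if window < max(scales):
        raise ValueError("window radius must cover the largest cell size")
    vol = np.asarray(intensity, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if vol.ndim == 2:
        vol = vol[..., None]
        mask = mask[..., None]

    d1 = np.diff(vol, axis=0)
    inc_sd = d1.std()
    work = vol * (gain / inc_sd) if inc_sd > 0 else vol

    size = 2 * window + 1
    areas = []
    for s in scales:
        a_s = np.empty_like(work)
        for z in range(work.shape[2]):
            grid = _prism_area_grid(work[:, :, z], s)
            # place each cell at its center, pad back to full shape
            full = np.pad(grid, ((s // 2, s - s // 2), (s // 2, s - s // 2)),
                          mode="edge")[: work.shape[0], : work.shape[1]]
            # mean cell area over the window, scaled to the window's tiling
            mean_area = ndimage.uniform_filter(full, size=size, mode="nearest")
            a_s[:, :, z] = mean_area * (size ** 2 / s ** 2)
        areas.append(a_s)

    slope = _loglog_slope(areas, np.asarray(scales, float))
    fd = np.clip(2.0 - slope, 2.0, 3.0)
    out = np.where(mask, fd, np.nan)
    if intensity.ndim == 2:
        out = out[..., 0]
    return FractalMap(values=out, kind="ptpsa", scales=scales, window=window)


# ----------------------------------------------------------------------
# Hölder exponent maps
# ----------------------------------------------------------------------

def _local_msd(vol: np.ndarray, lag: int, radius: int) -> np.ndarray:
    """Neighborhood-averaged mean squared increment at one lag."""
    sq_sum = np.zeros_like(vol)
    count = np.zeros_like(vol)
    for axis in range(vol.ndim):
        for sign in (+1, -1):
            d = np.zeros_like(vol)
            c = np.zeros_like(vol)
            sl_src = [slice(None)] * vol.ndim
            sl_dst = [slice(None)] * vol.ndim
            if sign > 0:
                sl_dst[axis] = slice(None, -lag)
                sl_src[axis] = slice(lag, None)
            else:
                sl_dst[axis] = slice(lag, None)
                sl_src[axis] = slice(None, -lag)
            d[tuple(sl_dst)] = (vol[tuple(sl_src)] - vol[tuple(sl_dst)]) ** 2
            c[tuple(sl_dst)] = 1.0
            sq_sum += d
            count += c
    size = 2 * radius + 1
    num = ndimage.uniform_filter(sq_sum, size=size, mode="constant", cval=0.0)
    den = ndimage.uniform_filter(count, size=size, mode="constant", cval=0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / den, 0.0)


def mbm_holder_map(intensity: np.ndarray, mask: np.ndarray,
                   lags: tuple = (1, 2, 4), radius: int = 4) -> FractalMap:
    """Hölder exponent map from local mean squared increments.

    Per voxel, log E|I(x+h) - I(x)|^2 (averaged over all axis directions
    and a cubic neighborhood of ``radius``) is regressed on log h;
    H(x) = slope / 2 clamped to [0, 1]. Voxels with zero local variance
    are flagged as perfectly smooth (H = 1) and logged.
    """
    lags = tuple(int(h) for h in lags)
    if len(lags) < 3:
        raise ValueError("need at least 3 lags")
    vol = np.asarray(intensity, dtype=float)
    if max(lags) >= min(vol.shape):
        raise ValueError("lags must fit inside the volume")
    mask = np.asarray(mask, dtype=bool)

    msds = [_local_msd(vol, h, radius) for h in lags]
    flat = msds[0] <= 0
    if np.any(flat & mask):
        log.info("mbm_holder_map: %d in-mask voxels have zero local variance; "
                 "flagged as H=1", int((flat & mask).sum()))
    slope = _loglog_slope(msds, np.asarray(lags, float))
    h_map = np.clip(slope / 2.0, 0.0, 1.0)
    h_map = np.where(flat, 1.0, h_map)
    out = np.where(mask, h_map, np.nan)
    return FractalMap(values=out, kind="mbm", scales=lags, window=radius)


def gmbm_holder_map(intensity: np.ndarray, mask: np.ndarray,
                    lags: tuple = (2, 4, 8)) -> FractalMap:
    """Hölder exponent map from local oscillations (max - min over balls).

    As :func:`mbm_holder_map` but with the oscillation
    osc_h(x) = max - min of I over the Chebyshev ball of radius h in
    place of the second moment; H(x) is the log-log slope, clamped.
    The default ball radii start at 2: single-voxel balls are dominated
    by discreteness and bias the oscillation slope upward.
    """
    lags = tuple(int(h) for h in lags)
    if len(lags) < 3:
        raise ValueError("need at least 3 lags")
    vol = np.asarray(intensity, dtype=float)
    if max(lags) >= min(vol.shape):
        raise ValueError("lags must fit inside the volume")
    mask = np.asarray(mask, dtype=bool)

    oscs = []
    for h in lags:
        size = 2 * h + 1
        mx = ndimage.maximum_filter(vol, size=size, mode="nearest")
        mn = ndimage.minimum_filter(vol, size=size, mode="nearest")
        oscs.append(mx - mn)
    flat = oscs[0] <= 0
    if np.any(flat & mask):
        log.info("gmbm_holder_map: %d in-mask voxels have zero oscillation; "
                 "flagged as H=1", int((flat & mask).sum()))
    slope = _loglog_slope(oscs, np.asarray(lags, float))
    h_map = np.clip(slope, 0.0, 1.0)
    h_map = np.where(flat, 1.0, h_map)
    out = np.where(mask, h_map, np.nan)
    return FractalMap(values=out, kind="gmbm", scales=lags, window=max(lags))


# ----------------------------------------------------------------------
# texture statistics on fractal maps
# ----------------------------------------------------------------------

_KIND_TAG = {"ptpsa": "ptpsa", "mbm": "mBm", "gmbm": "GmBm"}


def fractal_texture_features(fmap: FractalMap, mask: np.ndarray, config=None) -> dict:
    """Quantize a fractal map and run the texture-matrix statistics on it.

    Names are prefixed with the transform tag (``ptpsa``/``mBm``/``GmBm``),
    e.g. ``T1C_mBm_GLZSM_LargeZoneLowGrayEmphasis``.
    """
    from .texture import FeatureConfig, glzsm_features, gtsdm_features, ngtdm_features, quantize_region

    cfg = config or FeatureConfig()
    mask = np.asarray(mask, bool) & np.isfinite(fmap.values)
    tag = _KIND_TAG[fmap.kind]
    q = quantize_region(fmap.values, mask, cfg.n_levels)
    out = {}
    out.update(gtsdm_features(q, cfg.gtsdm_distance, per_direction=cfg.per_direction))
    out.update(ngtdm_features(q))
    out.update(glzsm_features(q))
    return {f"T1C_{tag}_{k}": v for k, v in out.items()}
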