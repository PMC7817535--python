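"""Canopy-height-model processing: pit closing, watershed growing spaces,
crown delineation and the nine per-tree crown metrics.

Watershed segmentation of the (inverted, Gaussian-smoothed) CHM yields one
growing-space polygon per detected tree, tiling the analysis area; the
crown is the connected region around the apex above a height rule, so that
CA_P <= GA_P with equality for gap-free growing spaces. Metrics:

==========  =====================================================  =====
CR          crown radius, sqrt(CA_P / pi)                          m
CL          apex height minus mean crown-boundary height           m
GA_P        growing-space (segment) projected area                 m^2
CA_P        crown projected area                                   m^2
A_CG        CA_P / GA_P                                            --
CS_C        triangulated area of the smoothed crown surface        m^2
CS_T        triangulated area of the raw crown surface             m^2
CV_F        volume between crown surface and the ground            m^3
CV_P        volume between crown surface and the crown base        m^3
==========  =====================================================  =====
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import linear_sum_assignment
from skimage.feature import peak_local_max
from skimage.morphology import closing, footprint_rectangle
from skimage.segmentation import watershed

from .raster import CHMRaster

__all__ = [
    "SegmentMap",
    "CrownRule",
    "CrownMetricSet",
    "close_pits",
    "segment_growing_spaces",
    "delineate_crowns",
    "compute_metrics",
    "crown_metrics_table",
    "match_trees",
]


def close_pits(chm: CHMRaster, kernel_size: int = 3) -> CHMRaster:
    """Remove single-cell data pits by grayscale morphological closing."""
    if kernel_size < 3 or kernel_size % 2 == 0:
        raise ValueError("kernel_size must be an odd integer >= 3")
    closed = closing(chm.values, footprint_rectangle((kernel_size, kernel_size)))
    return CHMRaster(values=closed, cell_size=chm.cell_size,
                     origin=chm.origin, nodata=chm.nodata)


@dataclass
class SegmentMap:
    """Watershed growing spaces: a label raster tiling the analysis area.

    ``apices`` has one row per segment: label, row, col, height (apex =
    segment maximum of the pit-closed CHM), x, y (apex cell centre).
    """

    labels: np.ndarray
    apices: pd.DataFrame
    cell_size: float
    origin: tuple[float, float]
    smoothed: np.ndarray

    @property
    def n_segments(self) -> int:
        return len(self.apices)


def segment_growing_spaces(chm: CHMRaster, smoothing_sigma: float = 1.5,
                           markers: Optional[np.ndarray] = None,
                           min_distance: float = 1.5,
                           min_height: float = 2.0) -> SegmentMap:
    """Marker-controlled watershed on the inverted smoothed CHM.

    ``smoothing_sigma`` is in cells. Markers default to local maxima of
    the smoothed CHM that dominate a ``min_distance``-metre window and at
    least ``min_height`` m tall; alternatively pass known stem positions
    as an (n, 2) array of map x/y. Every analysis (valid) cell is assigned
    to exactly one segment.
    """
    smoothed = ndimage.gaussian_filter(chm.values, smoothing_sigma)
    if markers is None:
        md = max(1, int(round(min_distance / chm.cell_size)))
        peaks = peak_local_max(smoothed, min_distance=md,
                               threshold_abs=min_height, exclude_border=False)
    else:
        pts = np.asarray(markers, dtype=float)
        r, c = chm.xy_to_rc(pts[:, 0], pts[:, 1])
        ok = (r >= 0) & (r < chm.shape[0]) & (c >= 0) & (c < chm.shape[1])
        peaks = np.column_stack([r[ok], c[ok]])
    if len(peaks) == 0:
        raise ValueError("no watershed markers found")
    marker_img = np.zeros(chm.shape, dtype=int)
    marker_img[peaks[:, 0], peaks[:, 1]] = np.arange(1, len(peaks) + 1)
    mask = chm.mask()
    labels = watershed(-smoothed, markers=marker_img, mask=mask)

    recs = []
    vals = np.where(mask, chm.values, -np.inf)
    for lbl in range(1, len(peaks) + 1):
        m = labels == lbl
        if not m.any():
            continue
        flat = np.where(m, vals, -np.inf)
        r, c = np.unravel_index(np.argmax(flat), flat.shape)
        x, y = chm.rc_to_xy(r, c)
        recs.append((lbl, int(r), int(c), float(vals[r, c]), float(x), float(y)))
    apices = pd.DataFrame(recs, columns=["label", "row", "col", "height", "x", "y"])
    return SegmentMap(labels=labels, apices=apices, cell_size=chm.cell_size,
                      origin=chm.origin, smoothed=smoothed)


@dataclass(frozen=True)
class CrownRule:
    """Crown membership rule: height >= max(min_height, apex_fraction * apex)."""

    min_height: float = 1.0
    apex_fraction: float = 0.3

    def threshold(self, apex_height: float) -> float:
        return max(self.min_height, self.apex_fraction * apex_height)


_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


def delineate_crowns(segments: SegmentMap, chm: CHMRaster,
                     rule: CrownRule = CrownRule()) -> np.ndarray:
    """Crown label raster: within each growing space, the 4-connected
    component of above-threshold cells that contains the apex. Gap-free
    segments yield crown == growing space."""
    crowns = np.zeros_like(segments.labels)
    for rec in segments.apices.itertuples(index=False):
        seg = segments.labels == rec.label
        thr = rule.threshold(rec.height)
        if chm.values[rec.row, rec.col] < thr:
            raise ValueError(f"crown rule excludes the apex of segment {rec.label}")
        cand = seg & (chm.values >= thr)
        comp, _ = ndimage.label(cand, structure=_CROSS)
        crowns[comp == comp[rec.row, rec.col]] = rec.label
    return crowns


def _corner_heights(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Grid-corner heights as the masked mean of adjacent cell centres."""
    v = np.where(mask, values, 0.0)
    vp = np.pad(v, 1)
    mp = np.pad(mask.astype(float), 1)
    s = vp[:-1, :-1] + vp[:-1, 1:] + vp[1:, :-1] + vp[1:, 1:]
    c = mp[:-1, :-1] + mp[:-1, 1:] + mp[1:, :-1] + mp[1:, 1:]
    with np.errstate(invalid="ignore"):
        return np.where(c > 0, s / np.maximum(c, 1), 0.0)


def _triangulated_area(values: np.ndarray, mask: np.ndarray, cs: float) -> float:
    """Surface area of the height field triangulated over masked cells.

    Each cell is split into two triangles on corner heights interpolated
    from crown cells only, so a flat crown of K cells has area K * cs^2.
    """
    corners = _corner_heights(values, mask)
    z00 = corners[:-1, :-1]
    z01 = corners[:-1, 1:]
    z10 = corners[1:, :-1]
    z11 = corners[1:, 1:]
    a1 = 0.5 * cs * np.sqrt((z01 - z00) ** 2 + (z10 - z00) ** 2 + cs ** 2)
    a2 = 0.5 * cs * np.sqrt((z11 - z10) ** 2 + (z11 - z01) ** 2 + cs ** 2)
    return float(((a1 + a2) * mask).sum())


@dataclass(frozen=True)
class CrownMetricSet:
    CR: float
    CL: float
    GA_P: float
    CA_P: float
    A_CG: float
    CS_C: float
    CS_T: float
    CV_F: float
    CV_P: float


def compute_metrics(chm: CHMRaster, segment_mask: np.ndarray,
                    crown_mask: np.ndarray,
                    smoothed: Optional[np.ndarray] = None) -> CrownMetricSet:
    """The nine crown metrics for one growing space / crown pair.

    ``smoothed`` supplies the smoothed surface for CS_C (defaults to the
    raw surface, making CS_C == CS_T)."""
    if not crown_mask.any():
        raise ValueError("empty crown")
    cs = chm.cell_size
    cell_area = cs * cs
    ga = float(segment_mask.sum()) * cell_area
    ca = float(crown_mask.sum()) * cell_area
    cr = float(np.sqrt(ca / np.pi))
    a_cg = ca / ga

    h = chm.values
    apex_h = float(h[crown_mask].max())
    interior = crown_mask & ndimage.binary_erosion(crown_mask, structure=_CROSS,
                                                   border_value=0)
    boundary = crown_mask & ~interior
    base = float(h[boundary].mean()) if boundary.any() else apex_h
    cl = apex_h - base
    cv_f = float(h[crown_mask].sum()) * cell_area
    cv_p = float(np.clip(h[crown_mask] - base, 0, None).sum()) * cell_area
    cs_t = _triangulated_area(h, crown_mask, cs)
    cs_c = _triangulated_area(smoothed if smoothed is not None else h, crown_mask, cs)
    return CrownMetricSet(CR=cr, CL=cl, GA_P=ga, CA_P=ca, A_CG=a_cg,
                          CS_C=cs_c, CS_T=cs_t, CV_F=cv_f, CV_P=cv_p)


def crown_metrics_table(chm: CHMRaster, segments: SegmentMap,
                        crowns: np.ndarray) -> pd.DataFrame:
    """Metrics for every segment, keyed by segment label, with apex x/y."""
    rows = []
    for rec in segments.apices.itertuples(index=False):
        seg = segments.labels == rec.label
        crn = crowns == rec.label
        m = compute_metrics(chm, seg, crn, smoothed=segments.smoothed)
        rows.append({"label": rec.label, "x": rec.x, "y": rec.y,
                     "apex_height": rec.height, **m.__dict__})
    return pd.DataFrame(rows)


def match_trees(detected: np.ndarray, planted: np.ndarray,
                max_dist: float) -> pd.DataFrame:
    """One-to-one least-squares matching of detected apices to planted stems.

    Optimal bipartite assignment minimising summed squared distance; pairs
    farther apart than ``max_dist`` are left unassigned. Returns a frame
    with detected index, planted index and distance; unmatched detections
    (potential segmentation errors) are the detected indices absent from it.
    """
    det = np.atleast_2d(np.asarray(detected, dtype=float))
    pla = np.atleast_2d(np.asarray(planted, dtype=float))
    if max_dist <= 0:
        raise ValueError("max_dist must be > 0")
    if len(det) == 0 or len(pla) == 0:
        return pd.DataFrame(columns=["detected", "planted", "distance"])
    d = np.hypot(det[:, None, 0] - pla[None, :, 0],
                 det[:, None, 1] - pla[None, :, 1])
    cost = d ** 2
    big = (max_dist ** 2) * 1e6 + 1.0
    cost = np.where(d > max_dist, big, cost)
    ri, ci = linear_sum_assignment(cost)
    keep = d[ri, ci] <= max_dist
    return pd.DataFrame({"detected": ri[keep], "planted": ci[keep],
                         "distance": d[ri, ci][keep]})
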