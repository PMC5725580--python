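"""Cell, edge, protrusion and leading-edge masks, plus boundary ROIs.

The mask chain reproduces a standard migrating-cell morphology analysis:
an intensity-threshold (or active-contour) cell mask is refined by light
morphology; the edge band is the cell minus a 10-pixel erosion; protrusions
are positive frame-to-frame mask differences tracked as spatiotemporal
connected components and kept when they are large (>= 2000 px footprint) and
persistent (>= 5 frames); the leading edge is the intersection of the edge
band with protruding regions.

Boundary ROIs are 1000 x 500 nm rectangles tiled along the cell boundary with
the long axis tangential to the membrane; matching cell-body ROIs reuse the
same long-axis angles but sit well inside the cell, so any orientation bias
of the segmentation geometry cancels between the two populations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import draw as skdraw
from skimage import measure, morphology, segmentation as skseg

from .angles import axis_angle_deg, fold180
from .polarimetry import BackgroundModel, _as_stack

__all__ = [
    "MaskSet",
    "SegmentROI",
    "segment_cells",
    "edge_mask",
    "detect_protrusions",
    "leading_edge",
    "boundary_rois",
]

EDGE_EROSION_PX = 10
PROTRUSION_MIN_AREA_PX = 2000
PROTRUSION_MIN_FRAMES = 5
SEED_DILATION_PX = 5
CLOSURE_RADIUS_PX = 1


def _per_frame(func, stack):
    stack3 = _as_stack(stack).astype(bool)
    out = np.stack([func(stack3[t]) for t in range(stack3.shape[0])])
    return out if np.ndim(stack) == 3 else out[0]


# --------------------------------------------------------------------------
# mask chain
# --------------------------------------------------------------------------

@dataclass
class MaskSet:
    """Per-frame binary masks of the chain cell ⊇ edge ⊇ leading edge."""

    cell: np.ndarray
    edge: np.ndarray
    protrusion: np.ndarray
    leading_edge: np.ndarray
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        self.cell = _as_stack(self.cell).astype(bool)
        self.edge = _as_stack(self.edge).astype(bool)
        self.protrusion = _as_stack(self.protrusion).astype(bool)
        self.leading_edge = _as_stack(self.leading_edge).astype(bool)
        shapes = {m.shape for m in (self.cell, self.edge, self.protrusion, self.leading_edge)}
        if len(shapes) != 1:
            raise ValueError("all masks must share shape")


def segment_cells(
    stack,
    bg: BackgroundModel,
    method: str = "threshold",
    min_object_px: int = 64,
    min_persistence_frames: int = 5,
) -> np.ndarray:
    """Per-frame cell mask from a total-intensity stack.

    Foreground seeds come from the background model (pixels above
    mu + 3 sigma), expanded by a 5-pixel dilation to include local background
    for contrast.  The mask is refined by a closure of radius one, small-object
    removal, and hole filling.  ``method='active_contour'`` additionally runs
    morphological Chan–Vese initialized from the dilated seed.  For movies,
    only cells consistently segmented for at least ``min_persistence_frames``
    (spatiotemporal connected components) are kept.
    """
    stack3 = _as_stack(stack)
    n_frames = stack3.shape[0]
    masks = np.zeros(stack3.shape, dtype=bool)
    selem = morphology.disk(CLOSURE_RADIUS_PX)
    for t in range(n_frames):
        frame = stack3[t]
        seed = bg.foreground_mask(frame)
        if not seed.any():
            continue
        region = morphology.dilation(seed, morphology.disk(SEED_DILATION_PX))
        if method == "threshold":
            m = seed
        elif method == "active_contour":
            m = skseg.morphological_chan_vese(
                frame * region, num_iter=50, init_level_set=seed.astype(np.int8)
            ).astype(bool)
            m &= region
        else:
            raise ValueError(f"unknown segmentation method: {method!r}")
        m = morphology.closing(m, selem)
        m = morphology.remove_small_objects(m, max_size=min_object_px - 1)
        m = ndimage.binary_fill_holes(m)
        masks[t] = m

    if not masks.any():
        warnings.warn("no foreground found; returning empty mask set")
        return masks if np.ndim(stack) == 3 else masks[0]

    if n_frames > 1:
        need = min(min_persistence_frames, n_frames)
        labels, n = ndimage.label(masks, structure=np.ones((3, 3, 3), dtype=int))
        keep = np.zeros(n + 1, dtype=bool)
        for lab in range(1, n + 1):
            frames_present = np.unique(np.nonzero(labels == lab)[0])
            keep[lab] = frames_present.size >= need
        masks = keep[labels]
    return masks if np.ndim(stack) == 3 else masks[0]


def edge_mask(cell, erosion_radius: int = EDGE_EROSION_PX):
    """Edge band: cell AND NOT erode(cell, radius).

    Returns ``(edge, degenerate)`` where ``degenerate`` flags frames whose
    cell is thinner than twice the erosion radius, for which the edge band is
    the whole cell.
    """
    cell3 = _as_stack(cell).astype(bool)
    if not cell3.any():
        raise ValueError("cell mask is empty")
    selem = morphology.disk(erosion_radius)
    edges = np.zeros_like(cell3)
    degenerate = np.zeros(cell3.shape[0], dtype=bool)
    for t in range(cell3.shape[0]):
        if not cell3[t].any():
            continue
        core = morphology.erosion(cell3[t], selem)
        if core.any():
            edges[t] = cell3[t] & ~core
        else:
            edges[t] = cell3[t]
            degenerate[t] = True
    if np.ndim(cell) == 2:
        return edges[0], bool(degenerate[0])
    return edges, degenerate


def detect_protrusions(
    cell_stack,
    min_area_px: int = PROTRUSION_MIN_AREA_PX,
    min_frames: int = PROTRUSION_MIN_FRAMES,
):
    """Detect persistent protrusions from frame-to-frame mask growth.

    Positive mask differences between neighboring frames are connected into
    spatiotemporal components (8-connectivity in space, 1-frame adjacency in
    time).  A component is a protrusion when its spatial footprint (union over
    time) covers at least ``min_area_px`` pixels and it spans at least
    ``min_frames`` frames.  Per-frame protrusion masks accumulate the kept
    components' growth up to that frame, intersected with the current cell.

    Returns ``(protrusion_stack, events)`` where each event is a dict with
    ``onset_frame``, ``area_px`` and ``n_frames``.
    """
    cell3 = _as_stack(cell_stack).astype(bool)
    n_frames = cell3.shape[0]
    if n_frames < 6:
        raise ValueError("protrusion detection needs at least 6 frames")
    diffs = cell3[1:] & ~cell3[:-1]          # growth entering at frame t+1
    labels, n = ndimage.label(diffs, structure=np.ones((3, 3, 3), dtype=int))
    out = np.zeros_like(cell3)
    events = []
    for lab in range(1, n + 1):
        voxels = labels == lab
        footprint = voxels.any(axis=0)
        frames_present = np.unique(np.nonzero(voxels)[0])
        span = int(frames_present[-1] - frames_present[0] + 1)
        area = int(np.count_nonzero(footprint))
        if area < min_area_px or span < min_frames:
            continue
        events.append({
            "onset_frame": int(frames_present[0] + 1),
            "area_px": area,
            "n_frames": span,
        })
        grown = np.zeros(cell3.shape[1:], dtype=bool)
        for t in range(n_frames):
            if t >= 1:
                grown |= voxels[t - 1]
            out[t] |= grown & cell3[t]
    if np.ndim(cell_stack) == 2:
        return out[0], events
    return out, events


def leading_edge(edge, protrusion):
    """Leading-edge mask: per-frame intersection of edge band and protrusion."""
    e = _as_stack(edge).astype(bool)
    p = _as_stack(protrusion).astype(bool)
    if e.shape != p.shape:
        raise ValueError("edge and protrusion masks must share shape")
    out = e & p
    return out if np.ndim(edge) == 3 else out[0]


# --------------------------------------------------------------------------
# boundary ROIs
# --------------------------------------------------------------------------

@dataclass
class SegmentROI:
    """Rectangular membrane ROI (long axis tangent to the boundary).

    ``tangent_deg`` and ``normal_deg`` are dipole-axis angles in [0, 180)
    (display convention, CCW, y up); ``outward_deg`` is the full-circle
    direction of the outward normal in [0, 360).
    """

    id: int
    center_xy: tuple[float, float]       # (col, row) px
    tangent_deg: float
    normal_deg: float
    outward_deg: float
    length_px: float
    width_px: float
    kind: str = "leading_edge"

    def __post_init__(self):
        if abs((self.normal_deg - self.tangent_deg) % 180.0 - 90.0) > 1e-6:
            raise ValueError("normal must be tangent + 90 deg (mod 180)")

    def corners_xy(self) -> np.ndarray:
        """4x2 array of rectangle corners as (x=col, y=row)."""
        cx, cy = self.center_xy
        th = np.radians(self.tangent_deg)
        tx, ty = np.cos(th), -np.sin(th)       # row axis points down
        nx, ny = -ty, tx
        L, W = self.length_px / 2.0, self.width_px / 2.0
        return np.array([
            [cx + L * tx + W * nx, cy + L * ty + W * ny],
            [cx + L * tx - W * nx, cy + L * ty - W * ny],
            [cx - L * tx - W * nx, cy - L * ty - W * ny],
            [cx - L * tx + W * nx, cy - L * ty + W * ny],
        ])

    def mask(self, shape) -> np.ndarray:
        """Rasterized rectangle footprint on an image of the given shape."""
        corners = self.corners_xy()
        rr, cc = skdraw.polygon(corners[:, 1], corners[:, 0], shape=shape)
        m = np.zeros(shape, dtype=bool)
        m[rr, cc] = True
        return m


def _largest_contour(mask2d: np.ndarray) -> np.ndarray:
    contours = measure.find_contours(mask2d.astype(float), 0.5)
    if not contours:
        raise ValueError("no boundary contour found")
    return max(contours, key=lambda c: c.shape[0])


def boundary_rois(
    cell_mask,
    pixel_size: float,
    kind: str = "leading_edge",
    roi_length_nm: float = 1000.0,
    roi_width_nm: float = 500.0,
    body_inset_nm: float = 1500.0,
    tangent_arc_nm: float = 500.0,
    anchor_xy: tuple[float, float] | None = None,
) -> list[SegmentROI]:
    """Tile 1000 x 500 nm rectangles along the cell boundary.

    The boundary contour is arc-length parameterized and divided into
    consecutive non-overlapping segments of ``roi_length_nm``; the leftover
    arc shorter than one ROI is dropped.  Tiling starts at the boundary point
    nearest ``anchor_xy`` (e.g. a protrusion centroid) when given.  The ROI
    long-axis (tangent) angle is the principal axis of the boundary points
    within ±``tangent_arc_nm`` of arc length; the normal is tangent + 90° with
    its outward sense fixed away from the cell centroid.

    ``kind='cell_body'`` keeps the same tangent angles but moves each center
    inward by ``body_inset_nm`` (> 1000 nm from the membrane); centers landing
    outside the cell are skipped.
    """
    mask2d = np.asarray(cell_mask).astype(bool)
    if mask2d.ndim != 2:
        raise ValueError("boundary_rois expects a single-frame mask")
    if not mask2d.any():
        raise ValueError("cell mask is empty")
    contour = _largest_contour(mask2d)          # (row, col), closed-ish
    if not np.allclose(contour[0], contour[-1]):
        contour = np.vstack([contour, contour[:1]])
    seg = np.diff(contour, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1]) * pixel_size   # nm
    arc = np.concatenate([[0.0], np.cumsum(seglen)])
    perimeter = arc[-1]
    n_rois = int(np.floor(perimeter / roi_length_nm))
    if n_rois == 0:
        return []

    if anchor_xy is not None:
        d2 = (contour[:-1, 1] - anchor_xy[0]) ** 2 + (contour[:-1, 0] - anchor_xy[1]) ** 2
        start_arc = arc[int(np.argmin(d2))]
    else:
        start_arc = 0.0

    rows, cols = np.nonzero(mask2d)
    centroid_xy = (cols.mean(), rows.mean())

    def point_at(s_nm: float) -> np.ndarray:
        s = s_nm % perimeter
        i = int(np.searchsorted(arc, s, side="right") - 1)
        i = min(i, len(seglen) - 1)
        frac = (s - arc[i]) / seglen[i] if seglen[i] > 0 else 0.0
        return contour[i] + frac * seg[i]

    def arc_points(center_s: float, half_nm: float) -> np.ndarray:
        step = max(pixel_size / 2.0, 1.0)
        ss = np.arange(center_s - half_nm, center_s + half_nm + step, step)
        return np.array([point_at(s) for s in ss])

    rois: list[SegmentROI] = []
    rid = 0
    for k in range(n_rois):
        s_mid = start_arc + (k + 0.5) * roi_length_nm
        pt = point_at(s_mid)                       # (row, col)
        pts = arc_points(s_mid, tangent_arc_nm)
        xy = pts[:, ::-1] - pts[:, ::-1].mean(axis=0)   # (x, y_row), centered
        _, _, vt = np.linalg.svd(xy, full_matrices=False)
        dx, dy_row = vt[0]
        tangent = axis_angle_deg(dx, dy_row)
        normal = fold180(tangent + 90.0)
        # outward sense: +/- normal direction with positive dot toward boundary
        nrad = np.radians(normal)
        nvec = np.array([np.cos(nrad), -np.sin(nrad)])      # (dx, drow)
        to_boundary = np.array([pt[1] - centroid_xy[0], pt[0] - centroid_xy[1]])
        if np.dot(nvec, to_boundary) < 0:
            nvec = -nvec
        outward = np.degrees(np.arctan2(-nvec[1], nvec[0])) % 360.0

        center = np.array([pt[1], pt[0]], dtype=float)      # (x, y)
        if kind == "cell_body":
            center = center - nvec * (body_inset_nm / pixel_size)
            ri, ci = int(round(center[1])), int(round(center[0]))
            if not (0 <= ri < mask2d.shape[0] and 0 <= ci < mask2d.shape[1]
                    and mask2d[ri, ci]):
                continue
        elif kind != "leading_edge":
            raise ValueError(f"unknown ROI kind: {kind!r}")

        rois.append(SegmentROI(
            id=rid,
            center_xy=(float(center[0]), float(center[1])),
            tangent_deg=float(tangent),
            normal_deg=float(normal),
            outward_deg=float(outward),
            length_px=roi_length_nm / pixel_size,
            width_px=roi_width_nm / pixel_size,
            kind=kind,
        ))
        rid += 1
    return rois
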