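"""End-to-end analysis chains: calibrate → segment → analyze → write.

Each modality has a library entry point returning an in-memory result bundle
(`analyze_ea`, `analyze_quad`, `analyze_flow`); `run_pipeline` wraps them
with file I/O, CSV/TIFF outputs and a provenance manifest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import flow as flowmod
from . import io as iomod
from . import molframe
from . import orientation as orientmod
from . import polarimetry as polmod
from . import segmentation as segmod

__all__ = [
    "EAResult",
    "QuadResult",
    "FlowResult",
    "analyze_ea",
    "analyze_quad",
    "analyze_flow",
    "run_pipeline",
]

REGION_KINDS = ("cell", "edge", "protrusion", "leading_edge")


def _mask_set(total_stack, bg, method="threshold"):
    cell = segmod.segment_cells(total_stack, bg, method=method)
    if not cell.any():
        return segmod.MaskSet(cell=cell, edge=np.zeros_like(cell),
                              protrusion=np.zeros_like(cell),
                              leading_edge=np.zeros_like(cell))
    edge, _ = segmod.edge_mask(cell)
    n_frames = cell.shape[0] if cell.ndim == 3 else 1
    if n_frames >= 6:
        prot, _ = segmod.detect_protrusions(cell)
    else:
        prot = np.zeros_like(cell)
    led = segmod.leading_edge(edge, prot)
    return segmod.MaskSet(cell=cell, edge=edge, protrusion=prot, leading_edge=led)


# --------------------------------------------------------------------------
# EA-TIRFM
# --------------------------------------------------------------------------

@dataclass
class EAResult:
    anisotropy: polmod.AnisotropyMap
    masks: segmod.MaskSet
    orientation: list          # per-frame OrientationMap
    fits: dict                 # region kind -> CosFitResult (or None)
    fourier: dict              # region kind -> FourierAmplitude (or None)
    background: polmod.BackgroundModel
    excluded_regions: list = field(default_factory=list)

    def fits_table(self) -> pd.DataFrame:
        rows = []
        for kind, f in self.fits.items():
            if f is None:
                continue
            rows.append({"region": kind, "C": f.C, "A": f.A,
                         "theta_d": f.theta_d, "R2": f.R2,
                         "n_pixels": f.n_pixels, "status": f.status})
        return pd.DataFrame(rows)


def analyze_ea(
    pair: polmod.PolarPairStack,
    prefilter: bool = True,
    bin_width: float = 10.0,
    fit_mode: str = "pixel",
    segmentation_method: str = "threshold",
    masks: segmod.MaskSet | None = None,
) -> EAResult:
    """Full EA-TIRFM chain: background, anisotropy, masks, cos² fits.

    Per region (cell, edge, protrusion, leading edge) the anisotropy of valid
    pixels is regressed on the distance-transform orientation map; regions
    failing the SNR ≥ 5 gate or the angular-coverage precondition are
    recorded in ``excluded_regions`` instead of fitted.
    """
    bg_perp = polmod.estimate_background(pair.I_perp)
    amap = polmod.anisotropy(pair, bg=bg_perp, prefilter=prefilter)
    if masks is None:
        total = pair.total_intensity
        bg_total = polmod.estimate_background(total)
        masks = _mask_set(total, bg_total, method=segmentation_method)
    omap = [orientmod.orientation_map(masks.cell[t]) if masks.cell[t].any() else None
            for t in range(masks.cell.shape[0])]

    perp_sub = polmod.subtract_background(pair.I_perp, bg_perp)
    fits: dict = {}
    fourier: dict = {}
    excluded: list = []
    for kind in REGION_KINDS:
        region_stack = getattr(masks, "protrusion" if kind == "protrusion" else kind)
        r_vals, g_vals = [], []
        snr_ok = False
        for t in range(region_stack.shape[0]):
            m = region_stack[t]
            if not m.any() or omap[t] is None:
                continue
            snr = polmod.region_snr(perp_sub[t][m], bg_perp)
            if snr < polmod.SNR_CUTOFF:
                continue
            snr_ok = True
            sel = m & amap.valid[t] & omap[t].valid
            r_vals.append(amap.r[t][sel])
            g_vals.append(omap[t].gamma[sel])
        if not r_vals:
            fits[kind] = None
            fourier[kind] = None
            if region_stack.any() and not snr_ok:
                excluded.append({"region": kind, "reason": "snr_below_cutoff"})
            continue
        r_all = np.concatenate(r_vals)
        g_all = np.concatenate(g_vals)
        try:
            fits[kind] = orientmod.cos2_fit(r_all, g_all, bin_width=bin_width,
                                            mode=fit_mode, kind=kind)
            fourier[kind] = orientmod.fourier_amplitude(r_all, g_all)
        except ValueError as exc:
            fits[kind] = None
            fourier[kind] = None
            excluded.append({"region": kind, "reason": str(exc)})
    return EAResult(anisotropy=amap, masks=masks, orientation=omap, fits=fits,
                    fourier=fourier, background=bg_perp, excluded_regions=excluded)


# --------------------------------------------------------------------------
# FluoPolScope
# --------------------------------------------------------------------------

@dataclass
class QuadResult:
    masks: segmod.MaskSet
    rois: list
    dipoles: list              # SegmentDipole
    histograms: dict           # kind -> RadialHistogram (or None)
    skipped_rois: list = field(default_factory=list)

    def dipole_table(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "roi_id": d.roi_id, "kind": d.kind, "theta_abs": d.theta_abs,
            "theta_d": d.theta_d, "p": d.p,
            "total_intensity": d.total_intensity, "isotropic": d.isotropic,
        } for d in self.dipoles])


def analyze_quad(
    quad: polmod.QuadStack,
    frame: int = 0,
    segmentation_method: str = "threshold",
    masks: segmod.MaskSet | None = None,
    body_inset_nm: float = 1500.0,
) -> QuadResult:
    """Full FluoPolScope chain: segment, tile boundary ROIs, per-ROI dipoles.

    Leading-edge ROIs (1000 × 500 nm, long axis tangential) are tiled along
    the cell boundary, anchored at the protrusion centroid when a protrusion
    was detected; cell-body ROIs reuse the same long-axis angles at
    ``body_inset_nm`` inside the membrane.  Radial histograms with circular-
    Gaussian fits are built per ROI population.
    """
    total = quad.total_intensity
    if masks is None:
        bg_total = polmod.estimate_background(total)
        masks = _mask_set(total, bg_total, method=segmentation_method)
    cell = masks.cell[frame]
    if not cell.any():
        raise ValueError("no cell segmented")

    anchor = None
    if masks.protrusion[frame].any():
        rows, cols = np.nonzero(masks.protrusion[frame])
        anchor = (cols.mean(), rows.mean())
    rois = segmod.boundary_rois(cell, quad.pixel_size, kind="leading_edge",
                                anchor_xy=anchor)
    rois += segmod.boundary_rois(cell, quad.pixel_size, kind="cell_body",
                                 body_inset_nm=body_inset_nm, anchor_xy=anchor)
    # keep ids unique across the two populations
    for i, roi in enumerate(rois):
        roi.id = i

    dipoles, skipped = [], []
    for roi in rois:
        try:
            dipoles.append(orientmod.segment_dipole(quad, roi, frame=frame))
        except ValueError as exc:
            skipped.append({"roi_id": roi.id, "reason": str(exc)})
    histograms = {}
    for kind in ("leading_edge", "cell_body"):
        sub = [d for d in dipoles if d.kind == kind]
        try:
            histograms[kind] = orientmod.radial_histogram(sub)
        except ValueError:
            histograms[kind] = None
    return QuadResult(masks=masks, rois=rois, dipoles=dipoles,
                      histograms=histograms, skipped_rois=skipped)


# --------------------------------------------------------------------------
# actin flow
# --------------------------------------------------------------------------

@dataclass
class FlowResult:
    field: flowmod.FlowField
    segment_flows: list
    histogram: pd.DataFrame | None
    direction_fit: flowmod.DirectionFit | None

    def flow_table(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "roi_id": f.roi_id, "speed_nm_s": f.speed_nm_s,
            "angle_to_tangent_deg": f.angle_to_tangent_deg,
            "direction_deg": f.direction_deg, "n_pixels": f.n_pixels,
        } for f in self.segment_flows])


def analyze_flow(
    stack,
    rois: Sequence[segmod.SegmentROI],
    pixel_size: float = 109.0,
    frame_interval: float = 1.0,
    **lk_params,
) -> FlowResult:
    """Optical flow over a movie, averaged per membrane ROI."""
    fieldf = flowmod.lucas_kanade_flow(stack, pixel_size=pixel_size,
                                       frame_interval=frame_interval, **lk_params)
    seg_flows = flowmod.flow_by_segment(fieldf, rois)
    hist, fit = None, None
    if len(seg_flows) >= 10:
        hist, fit = flowmod.direction_histogram(seg_flows)
    return FlowResult(field=fieldf, segment_flows=seg_flows, histogram=hist,
                      direction_fit=fit)


# --------------------------------------------------------------------------
# file-level pipeline
# --------------------------------------------------------------------------

def run_pipeline(config: iomod.RunConfig):
    """Execute a modality's full chain from files and write all outputs.

    Inputs are named in ``config.input_paths``: EA mode needs ``parallel``
    and ``perpendicular`` TIFFs; quad mode ``i0``/``i45``/``i90``/``i135``;
    flow mode ``movie``.  Outputs (CSV tables, float TIFF maps, manifest)
    land in ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    inputs = list(config.input_paths.values())
    p = config.params
    if config.modality == "ea":
        pair = polmod.PolarPairStack(
            I_par=iomod.read_stack(config.input_paths["parallel"]),
            I_perp=iomod.read_stack(config.input_paths["perpendicular"]),
            g_factor=p.get("g_factor", 1.0),
            pixel_size=config.pixel_size,
        )
        res = analyze_ea(pair, prefilter=p.get("prefilter", True),
                         bin_width=p.get("bin_width", 10.0),
                         fit_mode=p.get("fit_mode", "pixel"))
        res.fits_table().to_csv(out / "cos2_fits.csv", index=False)
        iomod.write_stack(out / "anisotropy.tif", res.anisotropy.r)
        iomod.write_stack(out / "masks_cell.tif",
                          res.masks.cell.astype(np.uint8))
    elif config.modality == "quad":
        chans = [iomod.read_stack(config.input_paths[k])
                 for k in ("i0", "i45", "i90", "i135")]
        quad = polmod.quad_calibrate(
            chans,
            throughput_factors=p.get("throughput_factors", (1.0, 1.0, 1.0, 1.0)),
            transforms=None,
            center_roi=tuple(p["center_roi"]) if "center_roi" in p else None,
            pixel_size=config.pixel_size,
        )
        res = analyze_quad(quad)
        res.dipole_table().to_csv(out / "segment_dipoles.csv", index=False)
        rows = []
        for kind, h in res.histograms.items():
            if h is None:
                continue
            rows.append({"kind": kind, "fit_mean_deg": h.fit_mean_deg,
                         "fit_sd_deg": h.fit_sd_deg, "mean_p": h.amplitude})
        pd.DataFrame(rows).to_csv(out / "radial_histograms.csv", index=False)
    elif config.modality == "flow":
        stack = iomod.read_stack(config.input_paths["movie"])
        total = stack
        bg = polmod.estimate_background(total)
        masks = _mask_set(total, bg)
        if masks.cell.any():
            rois = segmod.boundary_rois(masks.cell[0], config.pixel_size)
        else:
            warnings.warn("no cell segmented; flow reported without ROIs")
            rois = []
        res = analyze_flow(stack, rois, pixel_size=config.pixel_size,
                           frame_interval=config.frame_interval)
        res.flow_table().to_csv(out / "segment_flow.csv", index=False)
        if res.histogram is not None:
            res.histogram.to_csv(out / "direction_histogram.csv", index=False)
    elif config.modality == "frame":
        ens = molframe.read_ensemble_csv(config.input_paths["ensemble"])
        table = molframe.tilt_scan(
            ens,
            measured_theta_d=p["measured_theta_d"],
            measured_sd=p["measured_sd"],
            phi_grid=p.get("phi_grid", (11.25, 22.5, 45.0, 67.5)),
        )
        table.to_csv(out / "tilt_scan.csv", index=False)
        res = table
    else:  # pragma: no cover - RunConfig validates
        raise ValueError(config.modality)
    iomod.write_manifest(out, config, inputs=inputs)
    return res
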