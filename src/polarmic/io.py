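"""Channel registration, file I/O, and run configuration.

Image stacks travel as multi-page TIFF (one file per channel), tables as
CSV, and every analysis run writes a JSON manifest echoing all parameters,
the package version, the seed and input checksums, so two runs with
identical configuration and inputs produce identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage
from skimage import feature as skfeature
from skimage import registration as skreg
from skimage import transform as sktransform

__all__ = [
    "RegistrationResult",
    "RunConfig",
    "register_channels",
    "apply_transform",
    "read_stack",
    "write_stack",
    "write_manifest",
]


# --------------------------------------------------------------------------
# registration
# --------------------------------------------------------------------------

@dataclass
class RegistrationResult:
    """Affine map aligning a moving channel onto a fixed reference.

    ``transform`` maps moving-image coordinates (x, y) to fixed-image
    coordinates; apply it to the moving image with :func:`apply_transform`.
    """

    transform: sktransform.AffineTransform
    residual_px: float
    n_points: int
    method: str

    def apply(self, image) -> np.ndarray:
        return apply_transform(image, self.transform)


def apply_transform(image, tform) -> np.ndarray:
    """Warp an image (or stack) with a moving→fixed geometric transform."""
    img = np.asarray(image, dtype=float)
    if img.ndim == 3:
        return np.stack([apply_transform(f, tform) for f in img])
    return sktransform.warp(img, tform.inverse, order=3, mode="edge",
                            preserve_range=True)


def _detect_beads(image, min_distance: int = 5, threshold_rel: float = 0.2) -> np.ndarray:
    """Sub-pixel bead centroids as (x, y) via local maxima + center of mass."""
    img = ndimage.gaussian_filter(np.asarray(image, dtype=float), 1.0)
    peaks = skfeature.peak_local_max(img, min_distance=min_distance,
                                     threshold_rel=threshold_rel)
    pts = []
    h, w = img.shape
    for r, c in peaks:
        r0, r1 = max(r - 3, 0), min(r + 4, h)
        c0, c1 = max(c - 3, 0), min(c + 4, w)
        win = img[r0:r1, c0:c1]
        win = win - win.min()
        if win.sum() == 0:
            continue
        cr, cc = ndimage.center_of_mass(win)
        pts.append((c0 + cc, r0 + cr))
    return np.array(pts)


def register_channels(moving, fixed, method: str = "auto",
                      max_match_px: float = 10.0) -> RegistrationResult:
    """Estimate the affine transform aligning ``moving`` onto ``fixed``.

    ``method='beads'`` detects point sources in both images, pairs them by
    nearest neighbor (within ``max_match_px``), and solves a least-squares
    affine from ≥ 3 matches.  ``method='auto'`` uses sub-pixel intensity
    cross-correlation and returns a pure translation.
    """
    mov = np.asarray(moving, dtype=float)
    fix = np.asarray(fixed, dtype=float)
    if mov.shape != fix.shape:
        raise ValueError("images must share shape")
    if method == "auto":
        shift, error, _ = skreg.phase_cross_correlation(fix, mov, upsample_factor=100)
        tform = sktransform.AffineTransform(translation=(shift[1], shift[0]))
        if not np.isfinite(error):
            raise ValueError("cross-correlation failed")
        return RegistrationResult(transform=tform, residual_px=float(error),
                                  n_points=0, method="auto")
    if method != "beads":
        raise ValueError(f"unknown registration method: {method!r}")

    src = _detect_beads(mov)
    dst = _detect_beads(fix)
    if len(src) < 3 or len(dst) < 3:
        raise ValueError("fewer than 3 beads detected")
    pairs_src, pairs_dst = [], []
    for p in src:
        d = np.linalg.norm(dst - p, axis=1)
        j = int(np.argmin(d))
        if d[j] <= max_match_px:
            pairs_src.append(p)
            pairs_dst.append(dst[j])
    if len(pairs_src) < 3:
        raise ValueError(f"only {len(pairs_src)} bead matches (need >= 3)")
    src_m = np.array(pairs_src)
    dst_m = np.array(pairs_dst)
    tform = sktransform.AffineTransform.from_estimate(src_m, dst_m)
    if not tform:
        raise ValueError("affine estimation failed")
    resid = float(np.sqrt(np.mean(np.sum((tform(src_m) - dst_m) ** 2, axis=1))))
    return RegistrationResult(transform=tform, residual_px=resid,
                              n_points=len(src_m), method="beads")


# --------------------------------------------------------------------------
# files
# --------------------------------------------------------------------------

def read_stack(path) -> np.ndarray:
    """Read a multi-page TIFF as a float (T, H, W) stack."""
    arr = tifffile.imread(str(path)).astype(float)
    if arr.ndim == 2:
        arr = arr[None]
    return arr


def write_stack(path, stack) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(str(path), np.asarray(stack, dtype=np.float32),
                     photometric="minisblack")


def _checksum(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(out_dir, config: "RunConfig", inputs=(), extra=None) -> Path:
    """Write a machine-readable provenance manifest next to the outputs."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "polarmic",
        "version": __version__,
        "config": config.to_dict(),
        "inputs": {str(p): _checksum(p) for p in inputs if Path(p).exists()},
    }
    if extra:
        manifest["extra"] = extra
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Full parameterization of one analysis run.

    Every field is echoed verbatim into the output manifest.  ``params``
    carries module-level tunables (bin widths, window sizes, thresholds) that
    override the library defaults.
    """

    modality: str                      # ea | quad | flow | frame
    out_dir: str = "polarmic_out"
    input_paths: dict = field(default_factory=dict)
    pixel_size: float = 109.0          # nm
    frame_interval: float = 1.0        # s
    seed: int = 0
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.modality not in ("ea", "quad", "flow", "frame"):
            raise ValueError(f"unknown modality: {self.modality!r}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Load from JSON or TOML."""
        path = Path(path)
        if path.suffix == ".toml":
            import tomllib

            data = tomllib.loads(path.read_text())
        else:
            data = json.loads(path.read_text())
        return cls(**data)
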