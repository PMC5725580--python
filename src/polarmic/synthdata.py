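"""Synthetic scenes with ground truth for every analysis stage.

No raw microscopy data ship with this package; every pipeline is validated
on rendered scenes whose generating parameters are known exactly:

* EA-TIRFM pairs — a cell mask (disk, or disk growing a half-disk protrusion)
  whose per-pixel anisotropy follows r(γ) = C + A·cos²(γ − θd), with γ taken
  from the *same* distance-transform orientation map the analysis uses, so
  generation and analysis share one geometry definition.  The channel pair is
  rendered by inverting the anisotropy identity at a set total intensity.
* FluoPolScope quadruples — four analyzer channels
  I(α) = (I_tot/4)(1 + p·cos 2(α − θ)) with θ at a fixed offset θd from the
  local membrane normal.
* Flow movies — band-limited random texture rigidly translated (or advected
  radially inward) at a known velocity.
* Dipole ensembles — von Mises–Fisher draws about a mean axis with
  pseudo-energies, standing in for structure-prediction ensembles.

All generators are bit-for-bit reproducible from the seed, and with
``noise_model='none'`` are deterministic functions of the spec.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage
from skimage import morphology

from .molframe import DipoleEnsemble
from .orientation import orientation_map
from .polarimetry import PolarPairStack, QuadStack
from .angles import fold180

__all__ = [
    "SceneSpec",
    "GroundTruth",
    "make_ea_scene",
    "make_quad_scene",
    "make_flow_movie",
    "make_ensemble",
]


@dataclass
class SceneSpec:
    """Parameters of a rendered scene.

    ``total_intensity`` defaults to 100x the background standard deviation so
    that no pixel falls below the intensity gate in noiseless tests.
    """

    image_height: int = 128
    image_width: int = 128
    pixel_size: float = 109.0          # nm
    n_frames: int = 1
    cell_shape: str = "disk"           # disk | blob-with-protrusion
    baseline_C: float = 0.1            # anisotropy units
    amplitude_A: float = 0.05          # anisotropy units
    theta_d: float = 90.0              # degrees from the membrane normal
    total_intensity: float = 1000.0    # counts inside the cell
    background_mean: float = 100.0
    background_sd: float = 10.0
    noise_model: str = "none"          # none | gaussian | poisson
    seed: int = 0
    cell_radius_px: float | None = None
    protrusion_max_radius_px: float | None = None
    #: When set, the generating orientation field is snapped to this bin
    #: grid (degrees) before evaluating the cos² law, mirroring the binning
    #: step of the analysis so that ideal-image validation fits are exact.
    orientation_bin_width: float | None = None

    def __post_init__(self):
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.amplitude_A < 0:
            raise ValueError("amplitude_A must be >= 0")
        if self.background_sd < 0:
            raise ValueError("background_sd must be >= 0")
        if self.noise_model not in ("none", "gaussian", "poisson"):
            raise ValueError(f"unknown noise model: {self.noise_model!r}")
        if self.cell_shape not in ("disk", "blob-with-protrusion"):
            raise ValueError(f"unknown cell shape: {self.cell_shape!r}")
        lo = self.baseline_C
        hi = self.baseline_C + self.amplitude_A
        if lo < -0.5 or hi > 1.0:
            raise ValueError(
                f"anisotropy range [{lo}, {hi}] outside the representable [-0.5, 1]"
            )
        if self.cell_radius_px is None:
            self.cell_radius_px = 0.3 * min(self.image_height, self.image_width)
        if self.protrusion_max_radius_px is None:
            self.protrusion_max_radius_px = 0.55 * self.cell_radius_px

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """Per-pixel generating fields accompanying a rendered stack."""

    spec: SceneSpec
    cell_mask: np.ndarray                      # (T, H, W) bool
    orientation: np.ndarray | None = None      # γ, degrees [0, 180), NaN outside
    anisotropy: np.ndarray | None = None       # r field (EA mode)
    p: np.ndarray | None = None                # polarization factor (quad mode)
    theta: np.ndarray | None = None            # dipole axis field (quad mode)
    flow: np.ndarray | None = None             # (2, H, W): (vx, vy), display conv.

    def __post_init__(self):
        shape = self.cell_mask.shape
        for name in ("orientation", "anisotropy", "p", "theta"):
            f = getattr(self, name)
            if f is not None and f.shape != shape:
                raise ValueError(f"ground-truth field {name} shape mismatch")


# --------------------------------------------------------------------------
# cell geometry
# --------------------------------------------------------------------------

def _cell_mask(spec: SceneSpec, frame: int) -> np.ndarray:
    h, w = spec.image_height, spec.image_width
    cy, cx = h / 2.0, w / 2.0
    yy, xx = np.mgrid[0:h, 0:w]
    mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= spec.cell_radius_px**2
    if spec.cell_shape == "blob-with-protrusion":
        # half-disk bump growing eastward over frames
        if spec.n_frames > 1:
            frac = frame / (spec.n_frames - 1)
        else:
            frac = 1.0
        rb = spec.protrusion_max_radius_px * frac
        if rb > 0:
            bx, by = cx + spec.cell_radius_px, cy
            bump = ((yy - by) ** 2 + (xx - bx) ** 2 <= rb**2) & (xx >= bx)
            mask |= bump
    return mask


def _rng(spec: SceneSpec) -> np.random.Generator:
    return np.random.default_rng(spec.seed)


def _add_noise(stack: np.ndarray, spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.noise_model == "none":
        return stack
    if spec.noise_model == "gaussian":
        return stack + rng.normal(0.0, spec.background_sd, size=stack.shape)
    # shot-like noise
    return rng.poisson(np.clip(stack, 0, None)).astype(float)


# --------------------------------------------------------------------------
# EA-TIRFM scene
# --------------------------------------------------------------------------

def make_ea_scene(spec: SceneSpec) -> tuple[PolarPairStack, GroundTruth]:
    """Render a parallel/perpendicular pair with a cos² anisotropy field.

    The true anisotropy at each cell pixel is r(γ) = C + A·cos²(γ − θd) with
    γ from :func:`polarmic.orientation.orientation_map` of the rendered mask.
    Channels follow from inverting the anisotropy identity at the spec's
    total intensity: I_par = I_tot(1 + 2r)/3, I_perp = I_tot(1 − r)/3.
    """
    rng = _rng(spec)
    shape = (spec.n_frames, spec.image_height, spec.image_width)
    masks = np.zeros(shape, dtype=bool)
    gamma = np.full(shape, np.nan)
    r_true = np.full(shape, np.nan)
    i_par = np.zeros(shape)
    i_perp = np.zeros(shape)
    for t in range(spec.n_frames):
        masks[t] = _cell_mask(spec, t)
        if not masks[t].any():
            continue
        omap = orientation_map(masks[t])
        gamma[t] = omap.gamma
        if spec.orientation_bin_width:
            bw = spec.orientation_bin_width
            gamma[t] = fold180(np.round(gamma[t] / bw) * bw)
        r = np.full(masks[t].shape, np.nan)
        r[masks[t]] = spec.baseline_C
        ok = omap.valid & masks[t]
        r[ok] = spec.baseline_C + spec.amplitude_A * np.cos(
            np.radians(gamma[t][ok] - spec.theta_d)
        ) ** 2
        r_true[t] = r
        itot = np.where(masks[t], spec.total_intensity, 0.0)
        rr = np.where(np.isfinite(r), r, 0.0)
        i_par[t] = itot * (1.0 + 2.0 * rr) / 3.0
        i_perp[t] = itot * (1.0 - rr) / 3.0
    i_par += spec.background_mean
    i_perp += spec.background_mean
    i_par = _add_noise(i_par, spec, rng)
    i_perp = _add_noise(i_perp, spec, rng)
    pair = PolarPairStack(I_par=i_par, I_perp=i_perp, g_factor=1.0,
                          pixel_size=spec.pixel_size)
    gt = GroundTruth(spec=spec, cell_mask=masks, orientation=gamma,
                     anisotropy=r_true)
    return pair, gt


# --------------------------------------------------------------------------
# FluoPolScope scene
# --------------------------------------------------------------------------

def make_quad_scene(
    spec: SceneSpec,
    p_inside: float = 0.5,
    p_leading_edge: float | None = None,
    edge_band_px: int = 10,
    theta_jitter_sd: float = 0.0,
    randomize_body_theta: bool = False,
) -> tuple[QuadStack, GroundTruth]:
    """Render four analyzer channels with dipoles tied to the membrane normal.

    Each cell pixel carries a dipole axis θ = γ + θd (γ = local membrane
    normal axis from the orientation map), optionally jittered by a wrapped
    normal of ``theta_jitter_sd`` degrees.  ``p_leading_edge`` assigns a
    distinct polarization factor to the outer ``edge_band_px`` band so ordered
    edges over a disordered body can be emulated; ``randomize_body_theta``
    draws interior dipole axes uniformly at random.
    """
    for val in (p_inside, p_leading_edge):
        if val is not None and not (0.0 <= val <= 1.0):
            raise ValueError(f"polarization factor {val} outside [0, 1]")
    rng = _rng(spec)
    shape = (spec.n_frames, spec.image_height, spec.image_width)
    masks = np.zeros(shape, dtype=bool)
    gamma = np.full(shape, np.nan)
    theta_f = np.full(shape, np.nan)
    p_f = np.full(shape, np.nan)
    chans = [np.zeros(shape) for _ in range(4)]
    alphas = np.array([0.0, 45.0, 90.0, 135.0])
    for t in range(spec.n_frames):
        masks[t] = _cell_mask(spec, t)
        if not masks[t].any():
            continue
        omap = orientation_map(masks[t])
        gamma[t] = omap.gamma
        inside = masks[t]
        theta = fold180(np.where(np.isfinite(omap.gamma), omap.gamma, 0.0) + spec.theta_d)
        if theta_jitter_sd > 0:
            theta = fold180(theta + rng.normal(0.0, theta_jitter_sd, size=theta.shape))
        p_map = np.where(inside, p_inside, 0.0)
        if p_leading_edge is not None:
            core = morphology.erosion(inside, morphology.disk(edge_band_px))
            band = inside & ~core
            p_map[band] = p_leading_edge
            if randomize_body_theta:
                theta = np.where(core, rng.uniform(0, 180, size=theta.shape), theta)
        elif randomize_body_theta:
            theta = np.where(inside, rng.uniform(0, 180, size=theta.shape), theta)
        theta_f[t] = np.where(inside, theta, np.nan)
        p_f[t] = np.where(inside, p_map, np.nan)
        itot = np.where(inside, spec.total_intensity, 0.0)
        for i, a in enumerate(alphas):
            chans[i][t] = (itot / 4.0) * (
                1.0 + p_map * np.cos(np.radians(2.0 * (a - theta)))
            )
    for i in range(4):
        chans[i] = _add_noise(chans[i] + spec.background_mean, spec, rng)
    quad = QuadStack(*chans, pixel_size=spec.pixel_size)
    gt = GroundTruth(spec=spec, cell_mask=masks, orientation=gamma,
                     p=p_f, theta=theta_f)
    return quad, gt


# --------------------------------------------------------------------------
# flow movie
# --------------------------------------------------------------------------

def _texture(spec: SceneSpec, rng: np.random.Generator, scale_px: float) -> np.ndarray:
    noise = rng.normal(size=(spec.image_height, spec.image_width))
    tex = ndimage.gaussian_filter(noise, sigma=scale_px, mode="wrap")
    tex -= tex.min()
    tex /= max(tex.max(), 1e-12)
    return spec.background_mean + spec.total_intensity * tex


def _fft_shift(img: np.ndarray, drow: float, dcol: float) -> np.ndarray:
    """Exact sub-pixel rigid translation of a periodic image."""
    h, w = img.shape
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.fftfreq(w)[None, :]
    phase = np.exp(-2j * np.pi * (fy * drow + fx * dcol))
    return np.real(np.fft.ifft2(np.fft.fft2(img) * phase))


def make_flow_movie(
    spec: SceneSpec,
    velocity: float,
    direction_deg: float = 180.0,
    frame_interval: float = 1.0,
    texture_scale_px: float = 3.0,
    pattern: str = "uniform",
) -> tuple[np.ndarray, GroundTruth]:
    """Band-limited random texture moving at a known velocity.

    Parameters
    ----------
    velocity : float
        Speed in nm/s; the per-frame pixel shift is
        velocity * frame_interval / pixel_size and should be sub-pixel to a
        few pixels.
    direction_deg : float
        Motion direction, CCW from +x in display (y-up) convention.
    pattern : {'uniform', 'radial_inflow'}
        Rigid translation, or advection toward the image center at constant
        speed (retrograde-flow fixture).

    Ground truth stores the per-pixel (vx, vy) in px/frame, display
    convention.
    """
    if spec.n_frames < 2:
        raise ValueError("flow movies need at least 2 frames")
    rng = _rng(spec)
    shift = velocity * frame_interval / spec.pixel_size   # px / frame
    tex = _texture(spec, rng, texture_scale_px)
    h, w = tex.shape
    stack = np.empty((spec.n_frames, h, w))
    if pattern == "uniform":
        vx = shift * np.cos(np.radians(direction_deg))
        vy = shift * np.sin(np.radians(direction_deg))
        drow, dcol = -vy, vx
        for t in range(spec.n_frames):
            stack[t] = _fft_shift(tex, t * drow, t * dcol)
        flow = np.stack([np.full((h, w), vx), np.full((h, w), vy)])
    elif pattern == "radial_inflow":
        cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
        yy, xx = np.mgrid[0:h, 0:w].astype(float)
        rr = np.hypot(yy - cy, xx - cx)
        rr[rr == 0] = 1.0
        # unit outward vector in array coords
        ur, uc = (yy - cy) / rr, (xx - cx) / rr
        for t in range(spec.n_frames):
            # content moves inward: sample outward of the current position
            coords = np.stack([yy + t * shift * ur, xx + t * shift * uc])
            stack[t] = ndimage.map_coordinates(tex, coords, order=3, mode="wrap")
        vx = -shift * uc
        vy = shift * ur            # display vy = -array drow; drow = -shift*ur
        flow = np.stack([vx, vy])
    else:
        raise ValueError(f"unknown flow pattern: {pattern!r}")
    stack = _add_noise(stack, spec, rng)
    gt = GroundTruth(spec=spec, cell_mask=np.ones((spec.n_frames, h, w), dtype=bool),
                     flow=flow)
    return stack, gt


# --------------------------------------------------------------------------
# dipole ensembles
# --------------------------------------------------------------------------

def _sample_vmf(mu: np.ndarray, kappa: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """von Mises–Fisher samples on the unit sphere (Wood 1994)."""
    if kappa == 0:
        v = rng.normal(size=(n, 3))
        return v / np.linalg.norm(v, axis=1, keepdims=True)
    d = 3
    b = (-2.0 * kappa + np.sqrt(4.0 * kappa**2 + (d - 1) ** 2)) / (d - 1)
    x0 = (1.0 - b) / (1.0 + b)
    c = kappa * x0 + (d - 1) * np.log(1.0 - x0**2)
    ws = np.empty(n)
    for i in range(n):
        while True:
            z = rng.beta(0.5 * (d - 1), 0.5 * (d - 1))
            w = (1.0 - (1.0 + b) * z) / (1.0 - (1.0 - b) * z)
            u = rng.uniform()
            if kappa * w + (d - 1) * np.log(1.0 - x0 * w) - c >= np.log(u):
                ws[i] = w
                break
    v = rng.normal(size=(n, 2))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    samples = np.column_stack([np.sqrt(1.0 - ws**2) * v[:, 0],
                               np.sqrt(1.0 - ws**2) * v[:, 1],
                               ws])
    # rotate pole (0,0,1) onto mu
    mu = np.asarray(mu, dtype=float)
    mu = mu / np.linalg.norm(mu)
    pole = np.array([0.0, 0.0, 1.0])
    if np.allclose(mu, pole):
        return samples
    if np.allclose(mu, -pole):
        return -samples
    axis = np.cross(pole, mu)
    axis /= np.linalg.norm(axis)
    ang = np.arccos(np.clip(np.dot(pole, mu), -1.0, 1.0))
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    R = np.eye(3) + np.sin(ang) * K + (1 - np.cos(ang)) * (K @ K)
    return samples @ R.T


def make_ensemble(
    mean_direction,
    concentration: float,
    n: int,
    seed: int = 0,
) -> DipoleEnsemble:
    """Draw ``n`` unit dipoles about a mean axis with pseudo-energies.

    Dispersion decreases with ``concentration`` (von Mises–Fisher κ);
    κ = 0 gives isotropy.  Pseudo-energies increase with angular distance from
    the mean (plus seeded noise) so the lowest-40%-energy selection rule keeps
    the tighter members, as with structure-prediction score rankings.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if concentration < 0:
        raise ValueError("concentration must be >= 0")
    mu = np.asarray(mean_direction, dtype=float)
    mu = mu / np.linalg.norm(mu)
    rng = np.random.default_rng(seed)
    if n == 1 or concentration > 1e8:
        dipoles = np.tile(mu, (n, 1))
    else:
        dipoles = _sample_vmf(mu, concentration, n, rng)
    ang = np.degrees(np.arccos(np.clip(dipoles @ mu, -1.0, 1.0)))
    energies = ang + rng.normal(0.0, 1.0, size=n)
    return DipoleEnsemble(dipoles=dipoles, energies=energies)
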