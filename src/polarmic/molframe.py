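"""Molecular reference frame: atomic dipoles in microscope coordinates.

To compare a measured image-plane dipole angle with a structural model, the
atomic coordinates of a receptor–fluorophore fusion are placed in a frame
tied to the microscope: the ligand-attachment Cα defines the origin, the
line to the α-subunit junction Cα defines the +x axis (the direction of
lamellipodial movement, normal to the leading edge), and the β-subunit
junction Cα fixes the xz plane (z > 0, toward the cell).  The xy plane is
then parallel to the image plane.  For LFA-1 (αLβ2) the junction anchors are
the Cα of Arg-588 (αL β-propeller C-terminus) and Pro-104 (β2 βI-domain
N-terminus); the ligand point is the internal-ligand Glu Cα.

Molecular orientation is expressed in spherical angles: θ rotates the head
about z (in-plane), φ tilts it from the z axis; the reference state is
θ = 0°, φ = 90° (head axis in the image plane).  The fluorophore transition
dipole — for GFP, the published axis with slope (−0.026, 0.871, 0.439) in
the 1w7s chain-B frame, or the line through the Val-112 N atom and the
Asn-146 C / Ser-147 O midpoint — is carried along, projected onto the image
plane, and summed over a conformational ensemble (lowest 40% by energy) via
simulated four-analyzer intensities to give the ensemble dipole orientation
θ_ens and polarization factor p_ens.  A tilt scan compares θ_ens(φ) with a
measured θd ± sd band.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .angles import circ_dist180, fold180
from .polarimetry import quad_polarization

__all__ = [
    "MolecularFrame",
    "DipoleEnsemble",
    "OrientationState",
    "InPlaneProjection",
    "GFP_DIPOLE_SLOPE",
    "build_frame",
    "gfp_dipole_axis",
    "orient",
    "project_dipole",
    "ensemble_dipole",
    "tilt_scan",
    "read_ensemble_csv",
    "read_anchor_ca",
    "read_ensemble_pdb_dipoles",
]

#: GFP transition-dipole slope in the PDB 1w7s chain-B coordinate frame.
GFP_DIPOLE_SLOPE = (-0.026, 0.871, 0.439)

#: Atom triplet approximating the GFP dipole line: from Val-112 N to the
#: midpoint of Asn-146 C and Ser-147 O (1w7s numbering).
GFP_DIPOLE_ATOMS = (("VAL", 112, "N"), ("ASN", 146, "C"), ("SER", 147, "O"))

ENERGY_SELECT_FRACTION = 0.4


# --------------------------------------------------------------------------
# frame construction
# --------------------------------------------------------------------------

@dataclass
class MolecularFrame:
    """Rigid transform into the integrin–microscope frame: p' = R (p - t)."""

    rotation: np.ndarray     # (3, 3), rows are the frame axes
    translation: np.ndarray  # origin (ligand point) in input coordinates

    def apply(self, coords) -> np.ndarray:
        c = np.atleast_2d(np.asarray(coords, dtype=float))
        out = (c - self.translation) @ self.rotation.T
        return out if np.ndim(coords) == 2 else out[0]

    def apply_vector(self, vec) -> np.ndarray:
        """Rotate direction vectors (no translation)."""
        v = np.atleast_2d(np.asarray(vec, dtype=float))
        out = v @ self.rotation.T
        return out if np.ndim(vec) == 2 else out[0]


def build_frame(ligand_pt, alpha_junction, beta_junction) -> MolecularFrame:
    """Orthonormal right-handed frame from the three anchor Cα points.

    Origin at the ligand point; +x through the α-junction; the β-junction in
    the xz half-plane with z > 0.
    """
    lig = np.asarray(ligand_pt, dtype=float)
    a = np.asarray(alpha_junction, dtype=float) - lig
    b = np.asarray(beta_junction, dtype=float) - lig
    na = np.linalg.norm(a)
    if na == 0:
        raise ValueError("ligand point and alpha junction coincide")
    x = a / na
    z = b - np.dot(b, x) * x
    nz = np.linalg.norm(z)
    if nz < 1e-9 * max(np.linalg.norm(b), 1.0):
        raise ValueError("anchor points are collinear; frame undefined")
    z = z / nz
    y = np.cross(z, x)
    return MolecularFrame(rotation=np.vstack([x, y, z]), translation=lig)


# --------------------------------------------------------------------------
# dipole axis
# --------------------------------------------------------------------------

def gfp_dipole_axis(slope=None, atoms: Sequence = None) -> np.ndarray:
    """Unit GFP transition-dipole axis, with positive y component.

    Either from the published ``slope`` vector (1w7s chain-B frame) or from
    ``atoms`` = (Val112_N_xyz, Asn146_C_xyz, Ser147_O_xyz): the axis runs
    from the Val-112 N atom to the mean of the other two positions.
    """
    if (slope is None) == (atoms is None):
        raise ValueError("provide exactly one of slope or atoms")
    if slope is not None:
        v = np.asarray(slope, dtype=float)
    else:
        n112, c146, o147 = (np.asarray(p, dtype=float) for p in atoms)
        v = 0.5 * (c146 + o147) - n112
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length dipole axis")
    v = v / n
    if v[1] < 0:
        v = -v
    return v


# --------------------------------------------------------------------------
# ensembles
# --------------------------------------------------------------------------

@dataclass
class DipoleEnsemble:
    """Unit dipole vectors with energy scores.

    The working subset is the lowest ``ENERGY_SELECT_FRACTION`` by energy;
    ties at the cutoff are broken by input order (stable sort).
    """

    dipoles: np.ndarray      # (n, 3)
    energies: np.ndarray     # (n,)

    def __post_init__(self):
        self.dipoles = np.atleast_2d(np.asarray(self.dipoles, dtype=float))
        self.energies = np.asarray(self.energies, dtype=float).ravel()
        if self.dipoles.shape[0] != self.energies.shape[0]:
            raise ValueError("dipoles and energies must align")
        norms = np.linalg.norm(self.dipoles, axis=1)
        if np.any(norms == 0):
            raise ValueError("zero-length dipole")
        self.dipoles = self.dipoles / norms[:, None]

    def __len__(self) -> int:
        return self.dipoles.shape[0]

    def selected(self, fraction: float = ENERGY_SELECT_FRACTION) -> np.ndarray:
        """Dipoles of the lowest-energy ``fraction`` of members (>= 1)."""
        n = len(self)
        k = max(1, int(np.ceil(fraction * n)))
        order = np.argsort(self.energies, kind="stable")
        return self.dipoles[np.sort(order[:k])]


@dataclass
class OrientationState:
    """Spherical orientation of the molecule; reference is θ=0°, φ=90°."""

    theta: float = 0.0   # degrees, in-plane rotation about z
    phi: float = 90.0    # degrees, tilt of the head axis from +z

    def rotation(self) -> np.ndarray:
        # tilt about y by (90 - phi) keeps the alpha junction in the xz
        # plane; theta then rotates about z
        beta = np.radians(90.0 - self.phi)
        ry = np.array([[np.cos(beta), 0.0, np.sin(beta)],
                       [0.0, 1.0, 0.0],
                       [-np.sin(beta), 0.0, np.cos(beta)]])
        th = np.radians(self.theta)
        rz = np.array([[np.cos(th), -np.sin(th), 0.0],
                       [np.sin(th), np.cos(th), 0.0],
                       [0.0, 0.0, 1.0]])
        return rz @ ry


def orient(dipoles, state: OrientationState) -> np.ndarray:
    """Rotate framed dipoles into the given orientation state."""
    d = np.atleast_2d(np.asarray(dipoles, dtype=float))
    out = d @ state.rotation().T
    return out if np.ndim(dipoles) == 2 else out[0]


class InPlaneProjection(NamedTuple):
    angle_deg: float      # [0, 180); NaN for a purely axial vector
    magnitude: float


def project_dipole(vec) -> InPlaneProjection:
    """Image-plane projection of a 3-vector: folded angle and magnitude."""
    v = np.asarray(vec, dtype=float)
    if np.all(v == 0):
        raise ValueError("zero vector has no projection")
    mag = float(np.hypot(v[0], v[1]))
    if mag == 0:
        return InPlaneProjection(np.nan, 0.0)
    ang = fold180(np.degrees(np.arctan2(v[1], v[0])))
    return InPlaneProjection(float(ang), mag)


def ensemble_dipole(dipoles) -> tuple[float, float]:
    """Apparent (θ_ens, p_ens) of a dipole set via simulated intensities.

    Each member contributes I(α) = |projection|²·cos²(α − member angle) for
    α ∈ {0, 45, 90, 135}° (photoselection weight = squared in-plane
    magnitude); the channel sums are inverted through the four-analyzer
    identity.
    """
    d = np.atleast_2d(np.asarray(dipoles, dtype=float))
    mag2 = d[:, 0] ** 2 + d[:, 1] ** 2
    ok = mag2 > 0
    if not ok.any():
        raise ValueError("all ensemble members are axial; no in-plane signal")
    ang = np.degrees(np.arctan2(d[ok, 1], d[ok, 0]))
    w = mag2[ok]
    alphas = np.array([0.0, 45.0, 90.0, 135.0])
    sums = [float(np.sum(w * np.cos(np.radians(a - ang)) ** 2)) for a in alphas]
    qp = quad_polarization(*sums)
    return float(qp.theta_deg), float(qp.p)


def tilt_scan(
    ensemble: DipoleEnsemble,
    measured_theta_d: float,
    measured_sd: float,
    phi_grid: Sequence[float] = (11.25, 22.5, 45.0, 67.5),
    theta: float = 0.0,
) -> pd.DataFrame:
    """Scan tilts φ and flag consistency with a measured θd ± sd band.

    For each φ the selected (lowest-40%-energy) dipoles are rotated to
    (θ, φ), the ensemble dipole is projected, and the circular distance
    (period 180°) between θ_ens and the measured θd is compared with the
    measured standard deviation.
    """
    if len(phi_grid) == 0:
        raise ValueError("phi_grid must be non-empty")
    sel = ensemble.selected()
    rows = []
    for phi in phi_grid:
        th_ens, p_ens = ensemble_dipole(orient(sel, OrientationState(theta=theta, phi=phi)))
        dist = float(circ_dist180(th_ens, measured_theta_d))
        rows.append({
            "phi": float(phi),
            "theta_ens": th_ens,
            "p_ens": p_ens,
            "circ_dist": dist,
            "consistent": dist <= measured_sd,
        })
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# structural file I/O (gemmi)
# --------------------------------------------------------------------------

def read_ensemble_csv(path) -> DipoleEnsemble:
    """Load an ensemble table with columns dx, dy, dz, energy."""
    df = pd.read_csv(path)
    missing = {"dx", "dy", "dz", "energy"} - set(df.columns)
    if missing:
        raise ValueError(f"ensemble CSV missing columns: {sorted(missing)}")
    return DipoleEnsemble(
        dipoles=df[["dx", "dy", "dz"]].to_numpy(float),
        energies=df["energy"].to_numpy(float),
    )


def _gemmi_structure(path):
    import gemmi

    return gemmi.read_structure(str(path))


def read_anchor_ca(path, chain: str, resnum: int, model_index: int = 0) -> np.ndarray:
    """Cα position of one residue from a PDB/mmCIF file."""
    st = _gemmi_structure(path)
    model = st[model_index]
    for ch in model:
        if ch.name != chain:
            continue
        for res in ch:
            if res.seqid.num == resnum:
                atom = res.find_atom("CA", "*")
                if atom is None:
                    raise ValueError(f"residue {chain}/{resnum} has no CA atom")
                return np.array([atom.pos.x, atom.pos.y, atom.pos.z])
    raise ValueError(f"residue {chain}/{resnum} not found")


def read_ensemble_pdb_dipoles(path, chain: str | None = None,
                              atoms=GFP_DIPOLE_ATOMS,
                              energies=None) -> DipoleEnsemble:
    """Dipole axes from a multi-model PDB via the named GFP atoms per model.

    ``energies`` must align with the models; when omitted, zeros are used
    (selection then keeps the first 40% in model order).
    """
    st = _gemmi_structure(path)
    dipoles = []
    for model in st:
        pts = {}
        for ch in model:
            if chain is not None and ch.name != chain:
                continue
            for res in ch:
                for resname, num, aname in atoms:
                    if res.seqid.num == num and res.name == resname:
                        atom = res.find_atom(aname, "*")
                        if atom is not None:
                            pts[(resname, num, aname)] = np.array(
                                [atom.pos.x, atom.pos.y, atom.pos.z])
        missing = [a for a in atoms if a not in pts]
        if missing:
            raise ValueError(f"model {model.name}: missing atoms {missing}")
        dipoles.append(gfp_dipole_axis(atoms=[pts[a] for a in atoms]))
    dipoles = np.array(dipoles)
    if energies is None:
        energies = np.zeros(len(dipoles))
    return DipoleEnsemble(dipoles=dipoles, energies=energies)
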