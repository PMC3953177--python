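"""Coarse-grained kinematic chain model.

A protein conformation is represented by three backbone dihedral angles
(phi, psi, omega) per residue under the idealized-geometry assumption:
all covalent bond lengths and bond angles are fixed at standard values,
so a chain of n residues lives in a 3n-dimensional torsional space.
Cartesian coordinates for the modeled heavy atoms (N, CA, C, O, plus CB
for non-glycine residues) are obtained by forward kinematics (the NeRF
construction), and structural similarity is measured by the least RMSD
over CA atoms after optimal rigid-body (Kabsch) superposition.

Conventions
-----------
* Angles are stored in degrees in (-180, 180]; trigonometry is internal.
* Residue indexing is 1-based in every public interface.
* omega(i) is the peptide dihedral preceding residue i's N-CA bond,
  CA(i-1)-C(i-1)-N(i)-CA(i).  phi(1), omega(1) and psi(n) are stored but
  kinematically inert (they precede/follow the chain).
* Residue 1 is built in a canonical frame: N at the origin, CA on the
  +x axis, C in the xy-plane with positive y.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

ONE_LETTER_CODES = "ACDEFGHIKLMNPQRSTVWY"

THREE_TO_ONE = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
    "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
    "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
    "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

#: sentinel reported for kinematically inert terminal dihedrals
INERT = np.nan


class ChainError(ValueError):
    """Raised on invalid sequences, angles or coordinates."""


def validate_sequence(sequence: str) -> str:
    """Validate a one-letter amino-acid sequence and return it uppercased.

    Raises :class:`ChainError` naming the first offending index (1-based)
    if a code is not one of the 20 standard residues.
    """
    seq = str(sequence).strip().upper()
    for i, aa in enumerate(seq, start=1):
        if aa not in ONE_LETTER_CODES:
            raise ChainError(f"unknown residue code {aa!r} at position {i}")
    return seq


def wrap_angles(angles: np.ndarray) -> np.ndarray:
    """Wrap angles in degrees to the canonical interval (-180, 180]."""
    a = np.asarray(angles, dtype=float)
    wrapped = -np.mod(-a + 180.0, 360.0) + 180.0
    return wrapped


@dataclass(frozen=True)
class IdealGeometry:
    """Fixed covalent geometry of the backbone (lengths in Angstrom, angles
    in degrees).  Defaults are CHARMM22-style idealized values; they are
    constant for an entire run."""

    bond_n_ca: float = 1.458
    bond_ca_c: float = 1.525
    bond_c_n: float = 1.329      # peptide bond
    bond_c_o: float = 1.231      # carbonyl
    bond_ca_cb: float = 1.530

    angle_n_ca_c: float = 111.6
    angle_ca_c_n: float = 117.2
    angle_c_n_ca: float = 121.7
    angle_ca_c_o: float = 120.5
    angle_c_ca_cb: float = 110.1
    # improper dihedral N-C-CA-CB fixing L-chirality of the side chain
    improper_n_c_ca_cb: float = 122.6

    @classmethod
    def default(cls) -> "IdealGeometry":
        return cls()


@dataclass
class CoordinateSet:
    """Cartesian coordinates of the modeled atoms for a chain of n residues.

    ``backbone`` has shape (n, 4, 3) ordered N, CA, C, O; ``cb`` has shape
    (n, 3) with NaN rows for glycine.
    """

    sequence: str
    backbone: np.ndarray
    cb: np.ndarray

    @property
    def n_residues(self) -> int:
        return len(self.sequence)

    @property
    def n(self) -> np.ndarray:
        return self.backbone[:, 0]

    @property
    def ca(self) -> np.ndarray:
        return self.backbone[:, 1]

    @property
    def c(self) -> np.ndarray:
        return self.backbone[:, 2]

    @property
    def o(self) -> np.ndarray:
        return self.backbone[:, 3]

    def side_chain_centers(self) -> np.ndarray:
        """CB coordinates, with CA substituted for glycine."""
        out = self.cb.copy()
        gly = np.array([aa == "G" for aa in self.sequence])
        out[gly] = self.ca[gly]
        return out


@dataclass
class Conformation:
    """A sequence plus its dihedral state, with lazily realized coordinates
    and a cached energy.

    ``angles`` has shape (n, 3) ordered (phi, psi, omega), degrees in
    (-180, 180].  The array is frozen; producing a modified conformation
    goes through :meth:`with_angles`, which drops both caches.
    """

    sequence: str
    angles: np.ndarray
    coords: Optional[CoordinateSet] = None
    energy: Optional[float] = None
    generation: int = 0
    parent_id: Optional[int] = None
    geometry: IdealGeometry = field(default_factory=IdealGeometry.default)

    def __post_init__(self) -> None:
        self.sequence = validate_sequence(self.sequence)
        a = np.array(self.angles, dtype=float)
        if a.shape != (len(self.sequence), 3):
            raise ChainError(
                f"expected {len(self.sequence)}x3 angles, got shape {a.shape}"
            )
        a = wrap_angles(a)
        a.flags.writeable = False
        self.angles = a

    @property
    def n_residues(self) -> int:
        return len(self.sequence)

    def with_angles(self, angles: np.ndarray, **provenance) -> "Conformation":
        """Return a new conformation with replaced angles and empty caches.

        Skips re-validation of the (unchanged) sequence — this is the
        move operator's hot path.
        """
        child = object.__new__(Conformation)
        child.sequence = self.sequence
        a = wrap_angles(angles)
        a.flags.writeable = False
        child.angles = a
        child.coords = None
        child.energy = None
        child.generation = provenance.get("generation", self.generation)
        child.parent_id = provenance.get("parent_id", self.parent_id)
        child.geometry = self.geometry
        return child

    def realize(self) -> CoordinateSet:
        """Build (and cache) cartesian coordinates by forward kinematics."""
        if self.coords is None:
            self.coords = build_coordinates(self.angles, self.sequence,
                                            self.geometry)
        return self.coords


# ---------------------------------------------------------------------------
# Forward kinematics (NeRF; compiled kernel in _kernels.fk_batch)
# ---------------------------------------------------------------------------

import functools


@functools.lru_cache(maxsize=None)
def _pack_geometry(geo: IdealGeometry) -> np.ndarray:
    """Pack the geometry table for the compiled kernel (angles in rad)."""
    return np.array([
        geo.bond_n_ca, geo.bond_ca_c, geo.bond_c_n, geo.bond_c_o,
        geo.bond_ca_cb,
        np.deg2rad(geo.angle_n_ca_c), np.deg2rad(geo.angle_ca_c_n),
        np.deg2rad(geo.angle_c_n_ca), np.deg2rad(geo.angle_ca_c_o),
        np.deg2rad(geo.angle_c_ca_cb), np.deg2rad(geo.improper_n_c_ca_cb),
    ])


def build_coordinates_batch(angles: np.ndarray, sequence: str,
                            geometry: Optional[IdealGeometry] = None
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Forward kinematics for a batch of dihedral states.

    Parameters
    ----------
    angles : (m, n, 3) array of (phi, psi, omega) in degrees.
    sequence : one-letter sequence of length n shared by the batch.
    geometry : ideal covalent geometry; defaults to the shipped table.

    Returns
    -------
    backbone : (m, n, 4, 3) array ordered N, CA, C, O.
    cb : (m, n, 3) array, NaN for glycine.

    The first residue of every member is placed in the canonical frame
    (N at the origin, CA on +x, C in the xy-plane); the carbonyl O sits
    anti to the next residue's N, with the C-terminal O at the canonical
    dihedral 0 so terminal placement never depends on the inert psi(n).
    """
    from ._kernels import fk_batch

    geo = geometry or IdealGeometry.default()
    is_gly = _glycine_mask(sequence)
    ang = np.ascontiguousarray(angles, dtype=float)
    if ang.ndim != 3 or ang.shape[1] != len(sequence) or ang.shape[2] != 3:
        raise ChainError(
            f"expected (m, {len(sequence)}, 3) angles, got {ang.shape}")
    return fk_batch(ang, _pack_geometry(geo), is_gly)


@functools.lru_cache(maxsize=None)
def _glycine_mask(sequence: str) -> np.ndarray:
    seq = validate_sequence(sequence)
    return np.array([aa == "G" for aa in seq])


def build_coordinates(angles: np.ndarray, sequence: str,
                      geometry: Optional[IdealGeometry] = None
                      ) -> CoordinateSet:
    """Forward kinematics for a single dihedral state; see
    :func:`build_coordinates_batch`."""
    ang = np.asarray(angles, dtype=float)
    bb, cb = build_coordinates_batch(ang[None], sequence, geometry)
    return CoordinateSet(sequence=validate_sequence(sequence),
                         backbone=bb[0], cb=cb[0])


# ---------------------------------------------------------------------------
# Dihedral measurement (inverse kinematics)
# ---------------------------------------------------------------------------

def dihedral(p0, p1, p2, p3) -> float | np.ndarray:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, IUPAC convention
    (trans peptide = 180).  Broadcasts over leading axes."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1, axis=-1, keepdims=True)
    v = b0 - np.sum(b0 * b1n, axis=-1, keepdims=True) * b1n
    w = b2 - np.sum(b2 * b1n, axis=-1, keepdims=True) * b1n
    x = np.sum(v * w, axis=-1)
    y = np.sum(np.cross(b1n, v) * w, axis=-1)
    return wrap_angles(np.rad2deg(np.arctan2(y, x)))


def measure_dihedrals(coords: CoordinateSet) -> np.ndarray:
    """Measure (phi, psi, omega) per residue from backbone coordinates.

    Inert terminal angles — phi(1), omega(1), psi(n) — are reported as the
    NaN sentinel.  Raises :class:`ChainError` if a backbone atom is
    missing (NaN) for any residue.
    """
    bb = coords.backbone
    n = coords.n_residues
    if n < 1:
        raise ChainError("empty coordinate set")
    for i in range(n):
        for k, name in enumerate(("N", "CA", "C")):
            if not np.all(np.isfinite(bb[i, k])):
                raise ChainError(f"missing backbone atom {name} at residue {i + 1}")
    out = np.full((n, 3), INERT, dtype=float)
    if n >= 2:
        # phi(i) = C(i-1)-N(i)-CA(i)-C(i), i >= 2
        out[1:, 0] = dihedral(bb[:-1, 2], bb[1:, 0], bb[1:, 1], bb[1:, 2])
        # psi(i) = N(i)-CA(i)-C(i)-N(i+1), i <= n-1
        out[:-1, 1] = dihedral(bb[:-1, 0], bb[:-1, 1], bb[:-1, 2], bb[1:, 0])
        # omega(i) = CA(i-1)-C(i-1)-N(i)-CA(i), i >= 2
        out[1:, 2] = dihedral(bb[:-1, 1], bb[:-1, 2], bb[1:, 0], bb[1:, 1])
    return out


def extended_conformation(sequence: str,
                          geometry: Optional[IdealGeometry] = None
                          ) -> Conformation:
    """Fully extended trans conformation: every stored angle is 180 deg."""
    seq = validate_sequence(sequence)
    angles = np.full((len(seq), 3), 180.0)
    return Conformation(sequence=seq, angles=angles,
                        geometry=geometry or IdealGeometry.default())


# ---------------------------------------------------------------------------
# Least RMSD (Kabsch superposition over CA atoms)
# ---------------------------------------------------------------------------

def kabsch_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Optimal-superposition RMSD between two (k, 3) point sets, proper
    rotations only (no reflection)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ChainError(f"point sets must share shape (k, 3); got {a.shape} vs {b.shape}")
    if np.array_equal(a, b):
        return 0.0
    return float(kabsch_rmsd_batch(a[None], b[None])[0])


def kabsch_rmsd_batch(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Kabsch RMSD for batches of paired point sets, shapes (m, k, 3).

    The optimal proper rotation is applied explicitly and the residual
    measured, which is numerically stabler near zero than the
    singular-value trace identity.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    k = a.shape[1]
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    h = np.einsum("mki,mkj->mij", ac, bc)
    u, s, vt = np.linalg.svd(h)
    det = np.linalg.det(np.einsum("mij,mjk->mik", u, vt))
    # proper rotation only: flip the smallest singular direction if needed
    u = u.copy()
    u[:, :, -1] *= np.sign(det)[:, None]
    # R = V diag(1,1,d) U^T : R_ij = sum_l V_il U'_jl, V_il = vt_li
    rot = np.einsum("mli,mjl->mij", vt, u)
    resid = np.einsum("mij,mkj->mki", rot, ac) - bc
    return np.sqrt(np.einsum("mki,mki->m", resid, resid) / k)


def lrmsd(a: Conformation, b: Conformation) -> float:
    """Least RMSD (Angstrom) over CA atoms after Kabsch superposition.

    Symmetric, non-negative, invariant to rigid transforms of either
    input; raises on length mismatch.
    """
    if a.n_residues != b.n_residues:
        raise ChainError(
            f"length mismatch: {a.n_residues} vs {b.n_residues} residues")
    return kabsch_rmsd(a.realize().ca, b.realize().ca)


def lrmsd_to_coords(a: Conformation, ca_ref: np.ndarray) -> float:
    """Least RMSD of a conformation's CA trace against reference CA
    coordinates of shape (n, 3)."""
    return kabsch_rmsd(a.realize().ca, ca_ref)
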