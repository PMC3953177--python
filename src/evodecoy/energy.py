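"""Coarse-grained 5-term potential and the pluggable energy contract.

The potential scores a backbone-plus-CB conformation as the sum of five
non-local terms (local interactions carry no information under the
idealized-geometry assumption, since bond lengths and angles never move):

    E = E_LJ + E_hbond + E_compaction + E_burial + E_water

* ``E_LJ`` — 12-6 Lennard-Jones over all modeled atom pairs at sequence
  separation >= 2, with a soft repulsive core: below a fraction of the
  pair minimum distance the potential continues linearly, so steric
  overlap is penalized but always finite ("soft penetration" of van der
  Waals spheres).
* ``E_hbond`` — backbone hydrogen bonds: for donor N(i) / acceptor O(j)
  pairs at separation >= 3, a unit-peak Gaussian in the N...O distance
  times a cos^2 gate on the C=O...N angle (only angles beyond 90 deg
  contribute).  Always <= 0.
* ``E_compaction`` — a hinge on the CA radius of gyration above the
  globular target Rg = a * n^b; rewards collapse toward a compact core
  without over-rewarding it.
* ``E_burial`` — per-residue piecewise-linear wells on CB contact counts:
  hydrophobic residues are rewarded for being buried (high counts),
  polar residues for staying exposed (low counts).
* ``E_water`` — water-mediated pair interactions: class-dependent weights
  for CB pairs inside a 6.5-9.5 Angstrom shell, with a smooth cosine
  taper at both edges.

Energies are unitless scores; only their ordering matters for selection.
Every scoring call advances a shared :class:`BudgetCounter` by exactly
one — the global accounting that terminates a search run.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np

from .chain_model import Conformation, CoordinateSet, ChainError

# Binary hydrophobicity classes (H = hydrophobic, P = polar) from the
# Kyte-Doolittle scale: residues with positive hydropathy are class H.
HYDROPHOBIC = frozenset("ACFILMV")


def hydrophobicity_class(aa: str) -> str:
    return "H" if aa in HYDROPHOBIC else "P"


class BudgetExhausted(RuntimeError):
    """Raised when an evaluation is requested beyond a hard budget."""


@dataclass
class BudgetCounter:
    """Global energy-evaluation accounting.

    ``eval_count`` is monotone non-decreasing; it may exceed ``eval_max``
    only by the single in-flight evaluation that triggers the stop.
    """

    eval_max: Optional[int] = None
    eval_count: int = 0

    def tick(self) -> int:
        self.eval_count += 1
        return self.eval_count

    @property
    def exhausted(self) -> bool:
        return self.eval_max is not None and self.eval_count >= self.eval_max

    @property
    def remaining(self) -> Optional[int]:
        if self.eval_max is None:
            return None
        return max(0, self.eval_max - self.eval_count)


@dataclass(frozen=True)
class EnergyBreakdown:
    """The five term values and their total (total == sum of terms)."""

    e_lj: float
    e_hbond: float
    e_compaction: float
    e_burial: float
    e_water: float

    @property
    def total(self) -> float:
        return (self.e_lj + self.e_hbond + self.e_compaction
                + self.e_burial + self.e_water)

    def as_dict(self) -> dict:
        d = asdict(self)
        d["total"] = self.total
        return d


# Atom-type LJ parameters: r_min/2 radii (Angstrom) and well depths,
# AMBER-style values for backbone N, C(sp3), C(sp2), O and CB.
_LJ_RADIUS = {"N": 1.824, "CA": 1.908, "C": 1.908, "O": 1.661, "CB": 1.908}
_LJ_EPS = {"N": 0.170, "CA": 0.109, "C": 0.086, "O": 0.210, "CB": 0.109}


@dataclass(frozen=True)
class AMWParameters:
    """Versioned parameter table for the 5-term potential.

    All radii/distances in Angstrom; weights unitless.  Immutable for the
    duration of a run; serializable to/from a flat JSON object.
    """

    version: str = "1"
    # Lennard-Jones
    lj_softcore_fraction: float = 0.8     # cap at this fraction of r_min
    lj_min_separation: int = 2
    # Hydrogen bonds
    hbond_ideal_distance: float = 3.1     # ideal N...O distance
    hbond_distance_tolerance: float = 1.0  # hard cutoff on |d - d0|
    hbond_sigma: float = 0.4              # Gaussian width
    hbond_weight: float = 2.0
    hbond_min_separation: int = 3
    # Compaction: Rg_target = a * n^b
    compaction_weight: float = 0.5
    compaction_a: float = 2.2
    compaction_b: float = 0.38
    # Burial
    burial_shell_radius: float = 8.0
    burial_target_hydrophobic: int = 4    # desired minimum contact count
    burial_target_polar: int = 2          # desired maximum contact count
    burial_weight: float = 0.2
    burial_min_separation: int = 2
    # Water-mediated shell
    water_inner: float = 6.5
    water_outer: float = 9.5
    water_taper: float = 0.5
    water_weight_hh: float = -0.20
    water_weight_hp: float = -0.05
    water_weight_pp: float = -0.10
    water_min_separation: int = 2

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "AMWParameters":
        with open(path) as fh:
            return cls(**json.load(fh))

    def __post_init__(self):
        if not (0 < self.water_inner < self.water_outer):
            raise ValueError("water shell radii must satisfy 0 < inner < outer")
        if self.burial_shell_radius <= 0 or self.hbond_ideal_distance <= 0:
            raise ValueError("radii must be positive")


def _atom_table(coords: CoordinateSet):
    """Flatten the modeled atoms into (positions, residue index, type)."""
    n = coords.n_residues
    pos, resi, types = [], [], []
    for i in range(n):
        for k, name in enumerate(("N", "CA", "C", "O")):
            pos.append(coords.backbone[i, k])
            resi.append(i)
            types.append(name)
        if coords.sequence[i] != "G":
            pos.append(coords.cb[i])
            resi.append(i)
            types.append("CB")
    return np.array(pos), np.array(resi), types


def lj_term(coords: CoordinateSet, params: AMWParameters) -> float:
    """Soft-core 12-6 Lennard-Jones over atom pairs with residue
    separation >= ``lj_min_separation``.

    Per pair: eps_ij * [(r_min,ij / r)^12 - 2 (r_min,ij / r)^6] with
    r_min,ij the sum of the atom-type radii and eps_ij their geometric
    mean; below ``lj_softcore_fraction * r_min,ij`` the potential
    continues linearly with the slope at the cap, so it is continuous,
    monotone as r decreases, and finite down to r = 0.
    """
    from ._kernels import lj_kernel

    pos, resi, types = _atom_table(coords)
    rmin_half = np.array([_LJ_RADIUS[t] for t in types])
    eps = np.array([_LJ_EPS[t] for t in types])
    return float(lj_kernel(pos, resi, rmin_half, eps,
                           params.lj_min_separation,
                           params.lj_softcore_fraction))


def lj_pair_energy(r, rmin: float, eps: float, cap_fraction: float = 0.8
                   ) -> np.ndarray:
    """Soft-core 12-6 energy of a single pair at distance(s) ``r`` —
    the same kernel the full term sums over."""
    from ._kernels import lj_kernel

    rs = np.atleast_1d(np.asarray(r, dtype=float))
    out = np.empty_like(rs)
    resi = np.array([0, 2])
    half = np.array([rmin / 2.0, rmin / 2.0])
    eps_arr = np.array([eps, eps])
    for k, rk in enumerate(rs):
        pos = np.array([[0.0, 0.0, 0.0], [rk, 0.0, 0.0]])
        out[k] = lj_kernel(pos, resi, half, eps_arr, 2, cap_fraction)
    return out if np.ndim(r) else float(out[0])


def hbond_term(coords: CoordinateSet, params: AMWParameters) -> float:
    """Backbone N-H...O=C hydrogen-bond reward (always <= 0): for donor
    N(i) / acceptor O(j) pairs at sequence separation >=
    ``hbond_min_separation`` and within the distance tolerance, a
    unit-peak Gaussian at the ideal N...O distance times cos^2 of the
    C=O...N angle, gated to angles beyond 90 degrees."""
    from ._kernels import hbond_kernel

    return float(hbond_kernel(
        np.ascontiguousarray(coords.n), np.ascontiguousarray(coords.o),
        np.ascontiguousarray(coords.c),
        params.hbond_min_separation, params.hbond_ideal_distance,
        params.hbond_distance_tolerance, params.hbond_sigma,
        params.hbond_weight))


def radius_of_gyration(ca: np.ndarray) -> float:
    centered = ca - ca.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum(centered ** 2, axis=1))))


def compaction_term(coords: CoordinateSet, params: AMWParameters) -> float:
    """Hinge penalty on expansion beyond the globular Rg target."""
    rg = radius_of_gyration(coords.ca)
    target = params.compaction_a * coords.n_residues ** params.compaction_b
    return float(params.compaction_weight * max(0.0, rg - target) ** 2)


def _contact_counts(coords: CoordinateSet, radius: float, min_sep: int
                    ) -> np.ndarray:
    from ._kernels import contact_count_kernel

    centers = np.ascontiguousarray(coords.side_chain_centers())
    return contact_count_kernel(centers, min_sep, radius)


def burial_term(coords: CoordinateSet, params: AMWParameters) -> float:
    """Piecewise-linear burial wells on side-chain contact counts."""
    counts = _contact_counts(coords, params.burial_shell_radius,
                             params.burial_min_separation)
    total = 0.0
    for aa, c in zip(coords.sequence, counts):
        if aa in HYDROPHOBIC:
            total += params.burial_weight * max(
                0, params.burial_target_hydrophobic - int(c))
        else:
            total += params.burial_weight * max(
                0, int(c) - params.burial_target_polar)
    return float(total)


def water_term(coords: CoordinateSet, params: AMWParameters) -> float:
    """Class-weighted water-mediated pair interactions: each side-chain
    pair at sequence separation >= ``water_min_separation`` contributes
    its class weight (H/H, H/P or P/P) times a switching function equal
    to 1 inside [inner, outer] Angstrom with a cosine taper of width
    ``water_taper`` on both sides, 0 beyond."""
    from ._kernels import water_kernel

    centers = np.ascontiguousarray(coords.side_chain_centers())
    hydro = np.array([int(aa in HYDROPHOBIC) for aa in coords.sequence])
    return float(water_kernel(
        centers, hydro, params.water_min_separation,
        params.water_inner, params.water_outer, params.water_taper,
        params.water_weight_hh, params.water_weight_hp,
        params.water_weight_pp))


class EnergyModel:
    """Contract for pluggable fitness functions.

    Implementations provide :meth:`_breakdown`; scoring is deterministic
    given coordinates, rigid-transform invariant, and every call to
    :meth:`score` or :meth:`breakdown` advances the shared counter by
    exactly one (computing a breakdown alongside a total never
    double-counts: ``score`` is the breakdown's total).
    """

    def __init__(self, counter: Optional[BudgetCounter] = None):
        self.counter = counter if counter is not None else BudgetCounter()

    def _breakdown(self, conf: Conformation) -> EnergyBreakdown:
        raise NotImplementedError

    def breakdown(self, conf: Conformation) -> EnergyBreakdown:
        self.counter.tick()
        return self._breakdown(conf)

    def score(self, conf: Conformation) -> float:
        return self.breakdown(conf).total


class AMWEnergy(EnergyModel):
    """The 5-term coarse-grained potential as an :class:`EnergyModel`.

    Per-sequence static arrays (atom typing, hydrophobicity classes,
    burial targets) are cached so repeated scoring of the same chain —
    the search's hot path — only rebuilds coordinates and re-runs the
    pair kernels.  The fused path evaluates the same compiled kernels as
    the public per-term functions.
    """

    def __init__(self, params: Optional[AMWParameters] = None,
                 counter: Optional[BudgetCounter] = None):
        super().__init__(counter)
        self.params = params if params is not None else AMWParameters()
        self._static_cache: dict = {}

    def _static(self, sequence: str):
        cached = self._static_cache.get(sequence)
        if cached is None:
            n = len(sequence)
            not_gly = np.array([aa != "G" for aa in sequence])
            bb_types = ("N", "CA", "C", "O")
            resi = np.concatenate([np.repeat(np.arange(n), 4),
                                   np.arange(n)[not_gly]])
            types = [t for _ in range(n) for t in bb_types] + \
                    ["CB"] * int(not_gly.sum())
            rmin_half = np.array([_LJ_RADIUS[t] for t in types])
            eps = np.array([_LJ_EPS[t] for t in types])
            hydro = np.array([int(aa in HYDROPHOBIC) for aa in sequence])
            cached = (not_gly, resi, rmin_half, eps, hydro)
            self._static_cache[sequence] = cached
        return cached

    def _breakdown(self, conf: Conformation) -> EnergyBreakdown:
        try:
            coords = conf.realize()
        except ChainError as exc:
            raise ChainError(f"unrealizable conformation: {exc}") from exc
        from ._kernels import (contact_count_kernel, hbond_kernel,
                               lj_kernel, water_kernel)

        p = self.params
        not_gly, resi, rmin_half, eps, hydro = self._static(conf.sequence)
        bb = coords.backbone
        pos = np.concatenate([bb.reshape(-1, 3), coords.cb[not_gly]])
        e_lj = float(lj_kernel(pos, resi, rmin_half, eps,
                               p.lj_min_separation, p.lj_softcore_fraction))
        e_hb = float(hbond_kernel(
            np.ascontiguousarray(bb[:, 0]), np.ascontiguousarray(bb[:, 3]),
            np.ascontiguousarray(bb[:, 2]),
            p.hbond_min_separation, p.hbond_ideal_distance,
            p.hbond_distance_tolerance, p.hbond_sigma, p.hbond_weight))
        e_comp = compaction_term(coords, p)
        centers = np.where(not_gly[:, None], coords.cb, bb[:, 1])
        counts = contact_count_kernel(centers, p.burial_min_separation,
                                      p.burial_shell_radius)
        e_bur = float(np.sum(np.where(
            hydro == 1,
            p.burial_weight * np.maximum(0, p.burial_target_hydrophobic - counts),
            p.burial_weight * np.maximum(0, counts - p.burial_target_polar))))
        e_wat = float(water_kernel(
            centers, hydro, p.water_min_separation,
            p.water_inner, p.water_outer, p.water_taper,
            p.water_weight_hh, p.water_weight_hp, p.water_weight_pp))
        return EnergyBreakdown(e_lj=e_lj, e_hbond=e_hb, e_compaction=e_comp,
                               e_burial=e_bur, e_water=e_wat)


def score_total(conf: Conformation, params: Optional[AMWParameters] = None,
                counter: Optional[BudgetCounter] = None) -> float:
    """One-shot total energy; advances ``counter`` by 1 if given."""
    model = AMWEnergy(params=params, counter=counter)
    return model.score(conf)
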