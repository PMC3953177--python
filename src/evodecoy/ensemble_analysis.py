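"""Decoy-ensemble analytics.

The search algorithms emit a running ensemble Omega — the union of the
populations of every generation (the initial population included).  The
analytics here summarize such ensembles the way decoy-sampling studies
report them: the lowest lRMSD to a known native over the ensemble
(averaged and minimized over independent runs), the reduced ensemble
keeping only the best 5% by energy, energy-versus-lRMSD tables for
funnel plots, lRMSD histograms, and the per-population median pairwise
lRMSD used as a structural-diversity measure.

A decoy within 5 Angstrom of the native is flagged as having "captured"
the native basin at coarse-grained resolution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .chain_model import (
    Conformation,
    ChainError,
    IdealGeometry,
    build_coordinates_batch,
    kabsch_rmsd_batch,
    validate_sequence,
)

#: lRMSD (Angstrom) below which a decoy is considered to have captured
#: the native structure at coarse-grained resolution
CAPTURE_LRMSD = 5.0


class AnalysisError(ValueError):
    pass


@dataclass
class DecoyEnsemble:
    """The running decoy ensemble Omega of one run.

    Stores one record per decoy: its 3n dihedral angles, generation
    index, parent id and total energy.  ``|Omega| = pop_size x
    (completed generations + 1)`` for a single run, the initial
    population being generation 0.
    """

    sequence: str
    geometry: IdealGeometry = field(default_factory=IdealGeometry.default)
    _angles: List[np.ndarray] = field(default_factory=list)
    _energies: List[np.ndarray] = field(default_factory=list)
    _generations: List[np.ndarray] = field(default_factory=list)
    _parents: List[np.ndarray] = field(default_factory=list)

    def __post_init__(self):
        self.sequence = validate_sequence(self.sequence)

    def add_population(self, population: Sequence[Conformation],
                       generation: int) -> None:
        if any(c.energy is None for c in population):
            raise AnalysisError("all decoys must be scored before archiving")
        self._angles.append(np.stack([c.angles for c in population]))
        self._energies.append(np.array([c.energy for c in population]))
        self._generations.append(np.full(len(population), generation, dtype=int))
        self._parents.append(np.array(
            [-1 if c.parent_id is None else c.parent_id for c in population],
            dtype=int))

    def __len__(self) -> int:
        return int(sum(a.shape[0] for a in self._angles))

    @property
    def angles(self) -> np.ndarray:
        if not self._angles:
            raise AnalysisError("empty ensemble")
        return np.concatenate(self._angles)

    @property
    def energies(self) -> np.ndarray:
        if not self._energies:
            raise AnalysisError("empty ensemble")
        return np.concatenate(self._energies)

    @property
    def generations(self) -> np.ndarray:
        return np.concatenate(self._generations)

    @property
    def parent_ids(self) -> np.ndarray:
        return np.concatenate(self._parents)

    def conformation(self, index: int) -> Conformation:
        ang = self.angles[index]
        return Conformation(sequence=self.sequence, angles=ang,
                            energy=float(self.energies[index]),
                            generation=int(self.generations[index]),
                            geometry=self.geometry)

    # -- text archive -------------------------------------------------------

    def save_tsv(self, path, header_extra: str = "") -> None:
        """Write the angle archive: one row per decoy with id, generation,
        parent id, energy and the 3n angles at 6 decimals."""
        m = len(self)
        n = len(self.sequence)
        ang = self.angles.reshape(m, 3 * n)
        ene = self.energies
        gen = self.generations
        par = self.parent_ids
        with open(path, "w") as fh:
            fh.write(f"# evodecoy omega v1 n={n} size={m} "
                     f"sequence={self.sequence}"
                     + (f" {header_extra}" if header_extra else "") + "\n")
            fh.write("# id\tgeneration\tparent\tenergy\tangles...\n")
            for i in range(m):
                angles_s = " ".join(f"{a:.6f}" for a in ang[i])
                fh.write(f"{i}\t{gen[i]}\t{par[i]}\t{ene[i]:.9g}\t{angles_s}\n")

    @classmethod
    def load_tsv(cls, path) -> "DecoyEnsemble":
        with open(path) as fh:
            header = fh.readline().split()
            fields = dict(tok.split("=", 1) for tok in header if "=" in tok)
            seq = fields["sequence"]
            ens = cls(sequence=seq)
            rows = []
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                rows.append(line.rstrip("\n").split("\t"))
        if rows:
            gen = np.array([int(r[1]) for r in rows])
            ens._angles.append(np.array(
                [[float(x) for x in r[4].split()] for r in rows]
            ).reshape(len(rows), len(seq), 3))
            ens._energies.append(np.array([float(r[3]) for r in rows]))
            ens._generations.append(gen)
            ens._parents.append(np.array([int(r[2]) for r in rows]))
        return ens


def _ca_coords(angles: np.ndarray, sequence: str,
               geometry: Optional[IdealGeometry] = None,
               chunk: int = 2048) -> np.ndarray:
    """CA traces (m, n, 3) for a batch of dihedral states, built in
    chunks to bound memory."""
    out = []
    for lo in range(0, angles.shape[0], chunk):
        bb, _ = build_coordinates_batch(angles[lo:lo + chunk], sequence,
                                        geometry)
        out.append(bb[:, :, 1].copy())
    return np.concatenate(out)


def lrmsds_to_native(ensemble: DecoyEnsemble, native: Conformation
                     ) -> np.ndarray:
    """lRMSD of every decoy in the ensemble to the native structure."""
    if len(native.sequence) != len(ensemble.sequence):
        raise ChainError("native length does not match ensemble")
    ca = _ca_coords(ensemble.angles, ensemble.sequence, ensemble.geometry)
    ref = np.broadcast_to(native.realize().ca, ca.shape)
    return kabsch_rmsd_batch(ca, ref)


def lowest_lrmsd(ensemble: DecoyEnsemble, native: Conformation) -> float:
    """The lowest lRMSD to the native over the whole ensemble."""
    return float(np.min(lrmsds_to_native(ensemble, native)))


def lowest_lrmsd_summary(runs: Sequence[DecoyEnsemble], native: Conformation
                         ) -> tuple[float, float]:
    """(average, minimum) of the per-run lowest lRMSDs to the native."""
    if len(runs) == 0:
        raise AnalysisError("at least one run required")
    minima = [lowest_lrmsd(run, native) for run in runs]
    return float(np.mean(minima)), float(np.min(minima))


@dataclass
class ReducedEnsemble:
    """The best-5%-by-energy subset of an ensemble (Omega_p95)."""

    indices: np.ndarray
    energies: np.ndarray
    angles: np.ndarray
    rule: str = "lowest-energy 5%"

    def __len__(self) -> int:
        return len(self.indices)


def reduce_p95(ensemble: DecoyEnsemble, fraction: float = 0.05
               ) -> ReducedEnsemble:
    """Retain exactly ``ceil(fraction * |Omega|)`` lowest-energy decoys.

    The 95th percentile by energy is read as the best (lowest-energy)
    5%, since lower energy means higher fitness throughout; ties at the
    threshold break by decoy order (stable).
    """
    m = len(ensemble)
    if m == 0:
        raise AnalysisError("empty ensemble")
    keep = math.ceil(fraction * m)
    order = np.argsort(ensemble.energies, kind="stable")[:keep]
    order = np.sort(order)  # preserve decoy order within the subset
    return ReducedEnsemble(indices=order,
                           energies=ensemble.energies[order],
                           angles=ensemble.angles[order],
                           rule=f"lowest-energy {fraction:.0%}")


def median_pairwise_lrmsd(population, max_pairs: int = 50_000,
                          rng: Optional[np.random.Generator] = None,
                          sequence: Optional[str] = None,
                          geometry: Optional[IdealGeometry] = None) -> float:
    """Median lRMSD over all C(m, 2) pairs of a population — the
    structural-diversity measure.

    ``population`` is either a sequence of conformations or an (m, n, 3)
    angle array (then ``sequence`` is required).  When the exhaustive
    pair count exceeds ``max_pairs``, that many pairs are subsampled
    uniformly (requires ``rng``).
    """
    if isinstance(population, np.ndarray):
        if sequence is None:
            raise AnalysisError("sequence required with an angle array")
        angles = population
    else:
        population = list(population)
        if not population:
            raise AnalysisError("empty population")
        sequence = population[0].sequence
        geometry = population[0].geometry
        angles = np.stack([c.angles for c in population])
    m = angles.shape[0]
    if m < 2:
        raise AnalysisError("diversity needs at least 2 members")
    ca = _ca_coords(angles, sequence, geometry)
    n_pairs = m * (m - 1) // 2
    if n_pairs <= max_pairs:
        iu, ju = np.triu_indices(m, k=1)
    else:
        if rng is None:
            rng = np.random.default_rng(0)
        iu = rng.integers(0, m, size=max_pairs)
        shift = rng.integers(1, m, size=max_pairs)
        ju = (iu + shift) % m  # uniform over ordered distinct pairs
    return float(np.median(kabsch_rmsd_batch(ca[iu], ca[ju])))


def energy_vs_lrmsd_table(ensemble: DecoyEnsemble, native: Conformation
                          ) -> pd.DataFrame:
    """One row per decoy — id, generation, total energy, lRMSD to the
    native and the capture flag — sorted by lRMSD (funnel-plot data)."""
    lr = lrmsds_to_native(ensemble, native)
    df = pd.DataFrame({
        "decoy_id": np.arange(len(ensemble)),
        "generation": ensemble.generations,
        "energy": ensemble.energies,
        "lrmsd": lr,
        "captured": lr <= CAPTURE_LRMSD,
    })
    return df.sort_values("lrmsd", kind="stable").reset_index(drop=True)


def lrmsd_histogram(values, bin_width: float
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Bin lRMSD values into half-open bins [k*w, (k+1)*w).

    ``values`` is an array of lRMSDs (precomputed, e.g. by
    :func:`lrmsds_to_native`).  Returns (bin_left_edges, counts); counts
    sum to the input size.
    """
    if bin_width <= 0:
        raise AnalysisError("bin width must be positive")
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise AnalysisError("empty input")
    idx = np.floor(v / bin_width).astype(int)
    counts = np.bincount(idx)
    edges = np.arange(len(counts)) * bin_width
    return edges, counts
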