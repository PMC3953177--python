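"""Synthetic toy systems with planted targets and a separable toy energy.

A toy system plants a known target conformation inside a synthetic
fragment library: every 3-residue window of the library contains the
target's own 9-angle configuration (at a recorded index — the
reachability certificate), mixed with decoy configurations drawn from
Ramachandran basins.  Paired with :class:`ToyEnergy` — a separable sum
of squared angular deviations from the target, whose global minimum is
exactly 0 at the target — the whole search stack becomes testable
offline: the brute-force optimum over the library's reachable set is
enumerable for small chains, and recovery of the planted target is a
parameter-recovery analogue of finding a native structure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np

from .chain_model import Conformation, wrap_angles
from .energy import BudgetCounter, EnergyModel, EnergyBreakdown
from .fragments import (
    BasinSpec,
    FragmentError,
    FragmentLibrary,
    generate_synthetic_library,
    sample_basin_residues,
)

_AA_ALPHABET = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass
class ToySystem:
    """A sequence, a planted-target conformation, the synthetic library
    that can construct it, and the per-window certificate of where the
    planted entry sits."""

    sequence: str
    library: FragmentLibrary
    target: Conformation
    certificate: Dict[int, int]
    seed: Optional[int] = None


class ToyEnergy(EnergyModel):
    """Separable surrogate fitness: the weighted sum over all 3-residue
    windows of squared angular deviations (wrapped to +-180) between a
    conformation's window angles and per-window reference angles.

    Global minimum 0, attained iff the angles equal the reference.
    Separability makes the global optimum over any finite fragment
    library enumerable window by window.
    """

    def __init__(self, reference: np.ndarray, weight: float = 1.0,
                 counter: Optional[BudgetCounter] = None):
        super().__init__(counter)
        ref = wrap_angles(np.asarray(reference, dtype=float))
        if ref.ndim != 2 or ref.shape[1] != 3 or ref.shape[0] < 3:
            raise ValueError("reference must be (n >= 3, 3) angles")
        self.reference = ref
        self.weight = float(weight)
        # per-window (n-2, 9) view of the reference
        flat = ref.reshape(-1)
        self._ref_windows = np.lib.stride_tricks.sliding_window_view(
            flat, 9)[::3].copy()

    def window_deviation(self, angles: np.ndarray) -> np.ndarray:
        """Per-window sum of squared wrapped deviations (deg^2)."""
        flat = np.asarray(angles, dtype=float).reshape(-1)
        win = np.lib.stride_tricks.sliding_window_view(flat, 9)[::3]
        dev = wrap_angles(win - self._ref_windows)
        return np.sum(dev ** 2, axis=1)

    def _breakdown(self, conf: Conformation) -> EnergyBreakdown:
        if conf.n_residues != self.reference.shape[0]:
            raise ValueError("conformation/reference length mismatch")
        e = self.weight * float(np.sum(self.window_deviation(conf.angles)))
        # the toy surface is a single synthetic term; report it as such
        return EnergyBreakdown(e_lj=0.0, e_hbond=0.0, e_compaction=e,
                               e_burial=0.0, e_water=0.0)


def toy_energy_score(conf: Conformation, toy: ToyEnergy) -> float:
    """Score a conformation under the toy energy (counts one evaluation)."""
    return toy.score(conf)


def make_toy_system(n: int, entries_per_window: int = 3,
                    noise_spec: Optional[BasinSpec] = None,
                    seed: int = 0) -> ToySystem:
    """Build a deterministic toy system with a planted target.

    The target's per-residue angles are drawn from the basin mixture;
    each library window holds the target's own 9-angle slice plus
    ``entries_per_window - 1`` decoy configurations.
    """
    if n < 3:
        raise FragmentError("n >= 3 required")
    if entries_per_window < 1:
        raise FragmentError("entries_per_window >= 1 required")
    spec = noise_spec if noise_spec is not None else BasinSpec()
    rng = np.random.default_rng(seed)
    sequence = "".join(rng.choice(_AA_ALPHABET, size=n))
    target_angles = sample_basin_residues(spec, rng, n)
    planted = {w: target_angles[w - 1:w + 2].reshape(9)
               for w in range(1, n - 1)}
    library = generate_synthetic_library(
        n, spec=spec, rng=rng, entries_per_window=entries_per_window,
        planted=planted)
    certificate = {w: library.tags[w].index("planted")
                   for w in range(1, n - 1)}
    target = Conformation(sequence=sequence, angles=target_angles)
    return ToySystem(sequence=sequence, library=library, target=target,
                     certificate=certificate, seed=seed)
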