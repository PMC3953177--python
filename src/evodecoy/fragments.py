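"""Fragment-configuration libraries and the fragment-replacement move.

The move operator of the search: a window of 3 consecutive residues
[i, i+2] is chosen uniformly at random along the chain, and its 9
backbone dihedrals (phi, psi, omega) x 3 are overwritten with a 9-angle
configuration drawn uniformly from the configurations recorded for that
window in a fragment library.  Libraries may be extracted from known
structures (sliding 3-mer windows, pooled across positions by default)
or generated synthetically from Ramachandran basins, optionally with a
planted target configuration per window so that a designated
conformation is exactly constructible — the backbone of offline testing.

Library text format (TSV, 1-based window indices, angles at 6 decimals)::

    # fraglib v1 n=<n> policy=<policy>
    <window_start> \t phi1 psi1 omega1 phi2 psi2 omega2 phi3 psi3 omega3 \t <source_tag>
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np

from .chain_model import Conformation, measure_dihedrals, wrap_angles

# Ramachandran basin centers (phi, psi) in degrees
HELIX_BASIN = (-57.0, -47.0)
STRAND_BASIN = (-129.0, 124.0)


class FragmentError(ValueError):
    pass


@dataclass
class FragmentLibrary:
    """Per-window lists of 9-angle fragment configurations.

    ``windows`` maps window start i (1-based, i in [1, n-2]) to an array
    of shape (k_i, 9); every window of the target must be covered by at
    least one configuration.  ``tags`` carries a parallel source label
    per entry.
    """

    n_residues: int
    windows: Dict[int, np.ndarray]
    tags: Dict[int, List[str]] = field(default_factory=dict)
    source: str = "unspecified"
    seed: Optional[int] = None

    def __post_init__(self):
        n = self.n_residues
        if n < 3:
            raise FragmentError("a searchable chain needs n >= 3")
        expected = set(range(1, n - 1))
        if set(self.windows) != expected:
            missing = sorted(expected - set(self.windows))
            extra = sorted(set(self.windows) - expected)
            raise FragmentError(
                f"window keys must cover [1, {n - 2}]; "
                f"missing {missing}, unexpected {extra}")
        for w, arr in self.windows.items():
            arr = wrap_angles(np.atleast_2d(np.asarray(arr, dtype=float)))
            if arr.ndim != 2 or arr.shape[1] != 9 or arr.shape[0] < 1:
                raise FragmentError(
                    f"window {w}: expected a non-empty (k, 9) array")
            self.windows[w] = arr
            self.tags.setdefault(w, ["?"] * arr.shape[0])

    @property
    def n_windows(self) -> int:
        return self.n_residues - 2

    def entries(self, window_start: int) -> np.ndarray:
        try:
            return self.windows[window_start]
        except KeyError:
            raise FragmentError(f"no configurations for window {window_start}")

    def sample_move(self, rng: np.random.Generator) -> tuple[int, np.ndarray]:
        """Uniform window start in [1, n-2], uniform entry within it."""
        w = int(rng.integers(1, self.n_residues - 1))
        arr = self.windows[w]
        k = int(rng.integers(arr.shape[0]))
        return w, arr[k]

    # -- text serialization -------------------------------------------------

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# fraglib v1 n={self.n_residues} policy={self.source}\n")
            for w in sorted(self.windows):
                arr = self.windows[w]
                tags = self.tags[w]
                for row, tag in zip(arr, tags):
                    angles = " ".join(f"{a:.6f}" for a in row)
                    fh.write(f"{w}\t{angles}\t{tag}\n")

    @classmethod
    def from_tsv(cls, path) -> "FragmentLibrary":
        with open(path) as fh:
            header = fh.readline().strip()
            if not header.startswith("# fraglib v1"):
                raise FragmentError(f"not a v1 fragment library: {header!r}")
            fields = dict(tok.split("=", 1) for tok in header.split()[3:])
            n = int(fields["n"])
            windows: Dict[int, list] = {}
            tags: Dict[int, list] = {}
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                w_s, angles_s, tag = line.rstrip("\n").split("\t")
                w = int(w_s)
                windows.setdefault(w, []).append(
                    [float(x) for x in angles_s.split()])
                tags.setdefault(w, []).append(tag)
        return cls(n_residues=n,
                   windows={w: np.array(v) for w, v in windows.items()},
                   tags=tags, source=fields.get("policy", "file"))


def apply_fragment(angles: np.ndarray, window_start: int,
                   config: np.ndarray) -> np.ndarray:
    """Return a copy of an (n, 3) angle array with the 9 angles of the
    3-residue window starting at ``window_start`` (1-based) overwritten."""
    out = np.array(angles, dtype=float)
    i = window_start - 1
    out[i:i + 3] = np.asarray(config, dtype=float).reshape(3, 3)
    return out


def replace_fragment(conf: Conformation, lib: FragmentLibrary,
                     rng: np.random.Generator) -> Conformation:
    """One fragment-replacement move: a new conformation differing from
    the parent only in one window's 9 angles.  The parent is untouched
    and the child's coordinate/energy caches start empty."""
    if conf.n_residues != lib.n_residues:
        raise FragmentError(
            f"library built for n={lib.n_residues}, chain has {conf.n_residues}")
    w, config = lib.sample_move(rng)
    return conf.with_angles(apply_fragment(conf.angles, w, config))


def randomize_conformation(conf: Conformation, lib: FragmentLibrary,
                           rng: np.random.Generator) -> Conformation:
    """n - 2 fragment replacements swept over the chain: every window
    [w, w+2] for w = 1..n-2 receives a uniformly drawn configuration.

    From an extended chain this produces a random but realistic starting
    conformation; the sweep guarantees every residue is visited, so with
    single-entry windows the outcome is fully determined (a planted
    target is reproduced exactly).
    """
    if conf.n_residues != lib.n_residues:
        raise FragmentError(
            f"library built for n={lib.n_residues}, chain has {conf.n_residues}")
    angles = np.array(conf.angles, dtype=float)
    for w in range(1, conf.n_residues - 1):
        arr = lib.windows[w]
        angles = apply_fragment(angles, w, arr[int(rng.integers(arr.shape[0]))])
    return conf.with_angles(angles)


# ---------------------------------------------------------------------------
# Library construction
# ---------------------------------------------------------------------------

def library_from_angle_sets(angle_sets: Sequence[np.ndarray], n_target: int,
                            window_policy: str = "pooled",
                            tags: Optional[Sequence[str]] = None
                            ) -> FragmentLibrary:
    """Pool all sliding 3-mer windows of the given per-structure angle
    arrays into a library for a target of length ``n_target``.

    ``window_policy``:
      * ``"pooled"`` (default) — every target window receives the full
        pool of source 3-mers, position-independently.
      * ``"positional"`` — target window i receives only source window i
        (requires every source to be at least as long as the target).
    """
    tags = list(tags) if tags is not None else [
        f"src{k}" for k in range(len(angle_sets))]
    pool: list[np.ndarray] = []
    pool_tags: list[str] = []
    per_window: Dict[int, list] = {w: [] for w in range(1, n_target - 1)}
    per_window_tags: Dict[int, list] = {w: [] for w in range(1, n_target - 1)}
    for arr, tag in zip(angle_sets, tags):
        arr = np.asarray(arr, dtype=float)
        L = arr.shape[0]
        for i in range(L - 2):
            frag = arr[i:i + 3].reshape(9)
            if window_policy == "pooled":
                pool.append(frag)
                pool_tags.append(f"{tag}:{i + 1}")
            elif window_policy == "positional":
                w = i + 1
                if w in per_window:
                    per_window[w].append(frag)
                    per_window_tags[w].append(f"{tag}:{i + 1}")
            else:
                raise FragmentError(f"unknown window_policy {window_policy!r}")
    if window_policy == "pooled":
        if not pool:
            raise FragmentError("no usable 3-mers in the source structures")
        arr = np.array(pool)
        windows = {w: arr.copy() for w in range(1, n_target - 1)}
        wtags = {w: list(pool_tags) for w in range(1, n_target - 1)}
    else:
        if any(len(v) == 0 for v in per_window.values()):
            raise FragmentError("positional policy: some target windows "
                                "received no source 3-mers")
        windows = {w: np.array(v) for w, v in per_window.items()}
        wtags = per_window_tags
    return FragmentLibrary(n_residues=n_target, windows=windows, tags=wtags,
                           source=window_policy)


def build_library_from_structures(pdb_paths: Sequence[str], n_target: int,
                                  window_policy: str = "pooled"
                                  ) -> FragmentLibrary:
    """Measure 3-mer dihedral configurations from backbone PDB files and
    pool them into a library for a target of length ``n_target``.

    Inert terminal dihedrals of each source (which cannot be measured)
    are replaced by 180 deg so every sliding window yields 9 angles.
    """
    from .io_cli import read_pdb_backbone  # local import; io_cli binds the CLI

    angle_sets, tags = [], []
    for path in pdb_paths:
        _, coords = read_pdb_backbone(path)
        ang = measure_dihedrals(coords)
        ang = np.where(np.isnan(ang), 180.0, ang)
        if ang.shape[0] >= 3:
            angle_sets.append(ang)
            tags.append(str(path))
    if not angle_sets:
        raise FragmentError("no source structure contributed a usable 3-mer")
    return library_from_angle_sets(angle_sets, n_target, window_policy, tags)


# ---------------------------------------------------------------------------
# Synthetic libraries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BasinSpec:
    """Mixture over Ramachandran basins for synthetic configurations.

    Weights need not be normalized; zero total mass is rejected.  Noise
    is Gaussian on phi/psi (``sigma`` deg) and on omega around 180
    (``omega_sigma`` deg).
    """

    helix: float = 0.4
    strand: float = 0.3
    loop: float = 0.3
    sigma: float = 10.0
    omega_sigma: float = 2.0

    def weights(self) -> np.ndarray:
        w = np.array([self.helix, self.strand, self.loop], dtype=float)
        if w.sum() <= 0 or np.any(w < 0):
            raise FragmentError("basin mixture must have positive mass")
        return w / w.sum()


def _sample_phi_psi(spec: BasinSpec, rng: np.random.Generator,
                    size: int) -> np.ndarray:
    """Sample (size, 2) phi/psi pairs from the basin mixture."""
    which = rng.choice(3, size=size, p=spec.weights())
    out = np.empty((size, 2))
    for k, center in enumerate((HELIX_BASIN, STRAND_BASIN)):
        m = which == k
        out[m] = np.asarray(center) + rng.normal(0.0, spec.sigma, (int(m.sum()), 2))
    m = which == 2
    out[m] = rng.uniform(-180.0, 180.0, (int(m.sum()), 2))
    return out


def sample_basin_residues(spec: BasinSpec, rng: np.random.Generator,
                          n: int) -> np.ndarray:
    """Sample (n, 3) per-residue (phi, psi, omega) angles from the basins."""
    phipsi = _sample_phi_psi(spec, rng, n)
    omega = 180.0 + rng.normal(0.0, spec.omega_sigma, n)
    return wrap_angles(np.column_stack([phipsi, omega]))


def generate_synthetic_library(n: int, spec: Optional[BasinSpec] = None,
                               rng: Optional[np.random.Generator] = None,
                               entries_per_window: int = 10,
                               planted: Optional[Dict[int, np.ndarray]] = None,
                               seed: Optional[int] = None
                               ) -> FragmentLibrary:
    """Generate a synthetic fragment library from Ramachandran basins.

    If ``planted`` maps window starts to 9-angle configurations, each is
    inserted verbatim into its window (replacing one sampled entry), so a
    designated target conformation is exactly constructible.
    """
    spec = spec if spec is not None else BasinSpec()
    if rng is None:
        rng = np.random.default_rng(seed)
    if n < 3:
        raise FragmentError("n >= 3 required")
    if entries_per_window < 1:
        raise FragmentError("entries_per_window >= 1 required")
    windows: Dict[int, np.ndarray] = {}
    tags: Dict[int, List[str]] = {}
    for w in range(1, n - 1):
        entries = np.stack([
            sample_basin_residues(spec, rng, 3).reshape(9)
            for _ in range(entries_per_window)])
        wtags = ["synthetic"] * entries_per_window
        if planted is not None and w in planted:
            pos = int(rng.integers(entries_per_window))
            entries[pos] = wrap_angles(np.asarray(planted[w], dtype=float))
            wtags[pos] = "planted"
        windows[w] = entries
        tags[w] = wtags
    return FragmentLibrary(n_residues=n, windows=windows, tags=tags,
                           source="synthetic", seed=seed)
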