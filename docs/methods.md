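# Methods

## Problem setting

Stage one of de novo protein structure prediction is decoy sampling:
given only an amino-acid sequence, produce a *diverse* set of
sufficiently low-energy coarse-grained conformations (decoys) for later
all-atom refinement. Because coarse-grained energy functions are
approximate, the single Global Minimum Energy Conformation is explicitly
not the goal; a broad discrete picture of the low-energy landscape — many
distinct local minima — is. `evodecoy` implements two population-based
samplers for this task, a basic evolutionary algorithm (EA) and a memetic
EA (MEA), together with the chain model, move operator, energy terms and
ensemble analytics they require.

## Chain model

A conformation is the vector of backbone dihedrals (φ, ψ, ω) per residue
— 3n degrees of freedom for an n-residue chain — under the
idealized-geometry assumption: bond lengths and angles are fixed at
CHARMM22-style values (N–Cα 1.458 Å, Cα–C 1.525 Å, C–N 1.329 Å, C=O
1.231 Å, Cα–Cβ 1.530 Å; N–Cα–C 111.6°, Cα–C–N 117.2°, C–N–Cα 121.7°).
Heavy backbone atoms N, Cα, C, O are modeled explicitly; side chains are
reduced to Cβ (absent for glycine), placed by a fixed improper dihedral
N–C–Cα–Cβ = 122.6° that encodes L-chirality. Cartesian coordinates are
obtained by forward kinematics (the NeRF construction), residue 1 sitting
in a canonical frame (N at the origin, Cα on +x, C in the xy-plane).
With these values the trans-peptide Cα–Cα virtual bond is 3.813 Å.

Conventions fixed once and used everywhere:

* angles in degrees on (−180, 180], IUPAC dihedral signs (trans ω = 180);
* ω(i) is the peptide dihedral *preceding* residue i
  (Cα(i−1)–C(i−1)–N(i)–Cα(i)), so each residue owns exactly 3 angles;
  φ(1), ω(1) and ψ(n) are stored but kinematically inert and are
  reported as NaN by the dihedral-measurement routine;
* the carbonyl O sits anti to the next residue's N (dihedral ψ+180); the
  C-terminal O uses the canonical dihedral 0 so that terminal placement
  never depends on the inert ψ(n);
* the "extended" start conformation is all angles = 180 — the simplest
  reproducible choice; the n−2 randomizing fragment replacements that
  follow erase its details;
* residue indices are 1-based in every interface.

lRMSD is the unweighted Cα RMSD after optimal proper-rotation (Kabsch)
superposition, computed by applying the rotation and measuring the
residual (numerically stable near zero), with an exact-equality
shortcut so identical inputs report exactly 0. The literature sometimes
calls the post-alignment sum a "weighted" Euclidean distance without
stating weights; no weighting scheme being available, the standard
unweighted Cα lRMSD is implemented.

## Energy model

The fitness function is a sum of 5 non-local terms evaluated on the
coarse-grained coordinates. Their *intents* (soft steric exclusion,
backbone hydrogen bonding, hydrophobic collapse, burial preference,
water-mediated contacts) follow the associative-memory-with-water family
of potentials; the concrete functional forms below are this package's
own, chosen to be simple, bounded, and exactly testable against
brute-force oracles. All parameters live in one versioned, JSON-
serializable table (`AMWParameters`); energies are unitless scores —
only their ordering matters for selection, so no physical calibration is
attempted.

* **Lennard-Jones** — 12-6 with AMBER-style per-atom-type radii/depths
  (r_min,ij = sum of radii, ε_ij geometric mean), over atom pairs at
  residue separation ≥ 2. Below 0.8·r_min,ij the curve continues
  linearly with its slope at the cap: finite at r → 0, continuous, and
  monotone as r decreases ("soft penetration" of van der Waals spheres).
* **H-bond** — donor N(i)/acceptor O(j) pairs at separation ≥ 3 (so the
  i,i+4 helical bond is visible) contribute
  −w·exp(−(d−d₀)²/2σ²)·cos²θ, gated to C=O···N angles θ > 90° and to
  |d−d₀| ≤ 1 Å, with d₀ = 3.1 Å, σ = 0.4 Å, w = 2. The ideal distance
  sits near the N(i+4)···O(i) distance (3.18 Å) that the idealized
  α-helix (φ=−57, ψ=−47) produces under this chain model.
* **Compaction** — hinge on the Cα radius of gyration,
  w·max(0, Rg − 2.2·n^0.38)²: expansion beyond the standard globular
  scaling is penalized, collapse is never over-rewarded.
* **Burial** — per-residue piecewise-linear wells on Cβ contact counts
  within 8 Å (separation ≥ 2): hydrophobic residues (binary H class from
  the positive Kyte–Doolittle hydropathies A,C,F,I,L,M,V) are pushed
  toward ≥ 4 contacts, polar residues toward ≤ 2.
* **Water-mediated** — class-weighted Cβ pair contributions switched
  smoothly to 1 inside the 6.5–9.5 Å shell (cosine taper 0.5 Å), weights
  HH −0.20, HP −0.05, PP −0.10.

Under the default table the idealized 12-mer poly-alanine helix scores
−44.5 against +26.0 for the extended chain — the sanity direction of the
H-bond and compaction terms. The energy contract (`EnergyModel`) is
pluggable: scoring is deterministic given coordinates, rigid-transform
invariant, and every `score`/`breakdown` call advances one shared
`BudgetCounter` by exactly 1. Rosetta's *score3* is not reimplemented;
an external adapter can stand behind the same contract.

Hot paths (forward kinematics and the pair-term loops) are compiled with
numba; the public per-term functions and the fused scoring path call the
same kernels, so there is one implementation of each formula.

## Move operator and libraries

The only move is molecular fragment replacement: a 3-residue window
[i, i+2] with i uniform on [1, n−2], whose 9 dihedrals are overwritten
by a configuration drawn uniformly from that window's list in a fragment
library. Libraries are position-independent by default (every target
window sees the full pool of source 3-mers — the only defensible policy
for tiny source sets); a position-specific policy hook exists.
Duplicates are kept, so uniform sampling implicitly weights by observed
frequency. Libraries round-trip through a one-line-per-entry TSV.

Initial conformations are produced by a *sweep*: every window 1..n−2
receives one uniformly drawn configuration, in order. This is exactly
n−2 replacements, guarantees every residue is visited, and makes the
outcome fully determined when windows hold a single entry — the property
the synthetic planted-target machinery relies on. (Uniform random window
starts could leave terminal windows untouched.)

Synthetic libraries draw (φ, ψ) from a helix/strand/loop basin mixture
(centers (−57, −47) and (−129, 124); loop uniform) with Gaussian noise,
ω ~ 180 ± noise. Defaults: weights 0.4/0.3/0.3, σ = 10°, ω-σ = 2° —
roughly the proportions and within-basin spread of native 3-mers. A
*toy system* plants a target conformation: the target's own window
slices are inserted verbatim at recorded indices (the reachability
certificate), so the target is exactly constructible and recovery is a
parameter-recovery experiment with known truth.

## Search algorithms

Both algorithms evolve a fixed-size population P under a hard budget of
energy evaluations (generations are *not* fixed a priori):

1. parent selection by linear fitness weighting
   w_i = (E_max − E_i) + 0.01·(E_max − E_min); the 1% floor keeps the
   worst member selectable and the all-equal population degrades to
   uniform;
2. one fragment replacement per child (EA: 4000 children/generation by
   default; MEA: 250);
3. MEA only: each child is mapped to a nearby local minimum by greedy
   search — fragment replacements accepted only on *strict* energy
   decrease (strictness guarantees termination on finite libraries),
   halting after n consecutive rejections, every proposal costing one
   evaluation from the same budget;
4. truncation selection: the |P| lowest-energy members of parents ∪
   children survive, ties broken stably with parents first (mild,
   deterministic elitism); survivors are appended to the running decoy
   ensemble Ω (the initial population is generation 0 of Ω).

Budget semantics: the guard is checked before each child's first
evaluation; a greedy minimization in flight halts mid-search when the
counter reaches the budget and returns its best-so-far. If the budget
exhausts mid-generation, the already-scored children still compete in
that generation's truncation (no evaluation is wasted), so
|Ω| = |P|·(generations+1) always holds, and the final count can exceed
the budget by at most the one in-flight evaluation. A budget equal to
|P| yields exactly the initial population and zero generations.

All randomness flows from a single root seed through four independently
derived streams (initialization, parent selection, move proposals,
minimization), making runs bit-reproducible and the EA/MEA toggle
orthogonal to the other streams.

## Ensemble analytics

* lowest lRMSD to a native over Ω, averaged/minimized over runs;
* the reduced ensemble Ω_p95: exactly ceil(0.05·|Ω|) *lowest-energy*
  decoys (lower energy = higher fitness throughout, so "the 95th
  percentile by energy" is read as the best 5%; the opposite reading
  would discard precisely the decoys stage two needs), ties broken by
  decoy order;
* median pairwise Cα lRMSD of a population as the structural-diversity
  measure, exhaustive up to a 50,000-pair cap and uniformly subsampled
  beyond it (a 1000-member population has 499,500 pairs);
* energy-vs-lRMSD funnel tables and half-open-bin lRMSD histograms;
* decoys within 5 Å of the native are flagged as having "captured" it,
  the usual coarse-grained criterion.

## Bundled toy experiments and what they show

The regression experiments run at the benchmark population settings
(|P| = 1000, 250 children for MEA, 4000 for EA) with the evaluation
budget scaled down to desk size — 50,000 evaluations for the recovery
experiment (n = 20, 3 entries/window, separable toy energy) and 200,000
for the diversity contrast (n = 30, 5-term potential). At these sizes a
run takes seconds to about a minute on one core. Under the separable toy
energy the MEA reaches the planted target exactly (lowest lRMSD ~1e-15);
under the 5-term potential the EA's median pairwise lRMSD collapses from
~8.3 Å to 0 within ~20 of its 50 generations and never recovers, while
the MEA's 12 generations end with ~6.2 Å of diversity at comparable best
energies — the qualitative exploitative-vs-expansive contrast between
the two algorithms.

What the synthetic systems do *not* emulate: real Ramachandran
statistics beyond three idealized basins, sequence-dependent fragment
distributions, side chains beyond Cβ, or a physically calibrated
energy. Passing these tests certifies the *search machinery* (moves,
selection, minimization, accounting, analytics), not prediction
accuracy on real proteins; benchmark-scale runs (10M evaluations,
curated libraries, PDB natives) are supported by configuration but take
tens of CPU-hours per run.

## Numerical choices and edge cases

* Angle wrap to (−180, 180] everywhere; wrapped differences in the toy
  energy (so −175° vs +175° is a 10° deviation).
* The greedy halt after n consecutive rejections is a *working*
  definition of a local minimum; at very small n it can fire before the
  last improving move is sampled, so exact-optimum attainment checks are
  fixed-seed regressions rather than universal assertions.
* Truncation and p95 use stable argsorts — deterministic under ties.
* Unrealizable inputs (unknown residue codes, missing backbone atoms,
  empty library windows, length mismatches) are rejected with the
  offending index/atom named.
* PDB coordinates carry 3-decimal precision; structure round-trips are
  exact to ~1e-3 Å and dihedral round-trips through PDB to ~0.1°.

## Known limitations

* The 5-term parameterization is a defensible stand-in, not a published
  fit; absolute energies are not comparable to any published scale.
* Fragment libraries built from structures pool position-independently;
  sequence-profile-based picking is out of scope.
* No crossover, multi-objective guidance, clustering-based reduction or
  all-atom refinement — the scope is stage-one decoy sampling.
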