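# Methods

## Scope and data model

`efca` analyzes Ca²⁺ coordination by EF-hand domains along two tracks:
sequence-level characterization (domains, chemical classes,
identity/similarity, clustering, motif scanning) and trajectory-level
statistics (RMSD/RMSF, per-residue ion contact frequency, centre-of-mass
distance distributions). Trajectories are modelled as a `Topology` (ordered
atoms; residue groups; Ca²⁺ ion indices, identified by HETATM + element
`CA`, never by atom name) plus a stack of frames on a strictly uniform
stride. PDB files carry no time axis, so times are synthesized as
0, s, 2s, … from the declared stride (default 0.1 ns). Models are treated
as solvent-free fragments: there is no periodic-boundary handling, which is
a documented limitation for trajectories of solvated, wrapped systems.

## Sequence conventions

* Coordinates are 1-based inclusive throughout (`accession:start-end`).
* Residue classes partition the 20-letter alphabet: negative {D,E},
  positive {K,R,H} (His counted positive, following the Zappo scheme),
  polar {S,T,N,Q}, aromatic {F,W,Y}, hydrophobic {A,V,L,I,M}, Cys, Pro/Gly.
  `X` and unknown letters map to UNKNOWN. Net formal charge counts
  negative residues −1 and positive +1.
* **Percent identity** of a row pair uses as denominator the columns where
  at least one row is non-gap; the numerator counts identical non-gap
  pairs. **Percent similarity** shares the denominator and counts pairs
  that are identical *or* have a positive BLOSUM62 score. (The
  identity-included clause matters: BLOSUM62 scores X/X negatively, and
  similarity must dominate identity.) These are the most common pairwise
  conventions; published matrices from other tools may differ by their
  denominator choice, so exact reproduction of third-party percentages is
  not attempted.
* **Clustering** is UPGMA on distance = 100 − identity, with deterministic
  lexicographic tie-breaking on cluster labels. Merge heights are the
  average-linkage distances (two leaves merge *at* their distance); the
  Newick export places leaves at depth height/2. UPGMA is a surrogate for
  tree building generally — parsimony/bootstrap phylogenetics is out of
  scope — and is only required to reproduce group separation.
* The **EF-loop scan** matches every 12-residue window against the
  canonical loop pattern
  `D-x-[DNS]-{ILVFYW}-[DENSTG]-[DENQGHRK]-{GP}-[LIVMC]-[DENQSTAGC]-x-x-[DE]`
  (PROSITE-PS00018 style). Overlapping hits are reported; zero hits is a
  valid, reportable outcome.

## Trajectory statistics

* **Superposition** uses the Kabsch SVD solution with the determinant sign
  correction (reflections excluded). Degenerate selections (<3 atoms or
  collinear) raise a geometry error. The default selection is protein
  heavy atoms, consistent with the hydrogen-free distance rule; a Cα-only
  selection is available. Whether published RMSD traces used all heavy
  atoms or Cα only is generally unstated; both are supported.
* **RMSD** is evaluated against frame 0 after superposing each frame onto
  frame 0 over the selection.
* **RMSF** of residue r is √(mean over window frames and the residue's
  selected atoms of |x − x̄|²), where x̄ is the per-atom time mean within
  the window and all frames were superposed onto frame 0 first. The
  time-mean reference is the standard choice; the frame-0 superposition
  target mirrors the RMSD convention.
* **Stability** of an RMSD series is summarized as max − min over the
  analysis window; a series is stable when this fluctuation is ≤ 1 Å
  (configurable threshold).
* **Contact frequency**: per residue, the fraction of sampled frames in
  which the minimum distance between the residue's heavy atoms and any ion
  is ≤ the cutoff (default 5 Å, the distance at which Ca²⁺ can hydrogen-
  bond with charged/polar side chains or backbone carbonyls). Replicates
  are aggregated by pooling frames, i.e. frame-weighted; with equal-length
  replicates this equals averaging per-replicate frequencies, and the
  metadata records total_time_ns = n_replicates × last_ns.
* **COM distances**: mass-weighted centre of mass over the residue's heavy
  atoms (hydrogens excluded for consistency with the distance rule;
  `com_atoms="all"` includes them), distance to the nearest ion resolved
  per frame independently (ions are not identity-tracked). Quartiles use
  the linear-interpolation convention. Residues with mean distance > 9 Å
  are flagged non-coordinating; the flag filters nothing.
* **Window selection**: the analysis window takes frames with
  t > t_end − last_ns matched to a stride grid by nearest sample time, so
  a 5000-frame trajectory at 0.1 ns is exactly "the last 500 ns" even when
  its first frame sits at t = 0. A window longer than span + one stride is
  an error. Defaults: last_ns = 500, stride = 0.1 ns.
* **Position map**: alignment column c of a row maps to residue number =
  count of non-gap columns ≤ c; for a row with a single gap at column g
  this reduces to "subtract one for columns ≥ g", the rule needed to
  compare per-residue profiles across rows with deletions.

## Electrostatics surrogate

Binding-site electronegativity is scored with integer formal charges
(Asp/Glu −1, Lys/Arg +1, His neutral; termini ignored) placed at the
charged-group centroid (carboxylate O pair, Lys NZ, Arg guanidinium N)
when those atoms exist, else at the residue's heavy-atom COM (the Cα for
reduced models). A site score is the net charge within the site radius
plus the Coulomb potential Σ k·qᵢ/(ε·rᵢ) at the centre
(k = 332.06 kcal·Å·mol⁻¹·e⁻², uniform dielectric, default ε = 4, no
solvent screening). Only ordinal comparisons between sites are meaningful;
Poisson–Boltzmann surfaces are out of scope.

## Synthetic generators

* **Harmonic-well ion**: overdamped (Brownian) Langevin dynamics in an
  isotropic well, x_{n+1} = (1 − kΔt/ζ)x_n + √(2k_BTΔt/ζ)ξ_n, with
  stiffness k (kcal·mol⁻¹·Å⁻²), T = 300 K, friction coefficient ζ
  (kcal·mol⁻¹·ps·Å⁻², default 1), Δt = 0.1 ps. Overdamped rather than
  inertial dynamics keeps the stationary law exact and simple: the radius
  is chi(3)·σ with σ = √(k_BT/k), so P(r ≤ c) =
  erf(x/√2) − √(2/π)·x·e^(−x²/2), x = c/σ. A burn-in of 10 relaxation
  times (τ = ζ/k) is discarded. The Euler–Maruyama accuracy guard rejects
  kΔt/ζ ≥ 0.1 (the chain's stationary variance is inflated by
  1/(1 − kΔt/2ζ); the guard keeps that bias under ~5%, well below the
  statistical tolerance of the recovery checks). The recursion is linear,
  so it is evaluated exactly with an IIR filter; trajectories are
  bit-reproducible per seed.
* **Two-state ion**: i.i.d. per-frame Bernoulli placement at
  bound/unbound distance from a target residue. Dwell-time correlation is
  deliberately absent — it does not affect a frequency estimator's
  expectation and keeps the oracle exact: the generator records its own
  bound count, which the estimator must reproduce exactly.
* **Noise trajectories**: per-atom isotropic Gaussian displacement with
  per-residue σ about a base structure; expected RMSF = σ√3. Frame 0 is
  emitted unperturbed so that the frame-0 RMSD reference is the base
  structure and the series concentrates near σ√3 (for the RMSF this
  introduces an O(1/n) bias from the one clean frame, negligible at the
  frame counts used).
* **Fixtures**: a TPC1-like 77-residue EF-hand-like sequence with two
  acidic canonical loops (both match the EF-loop pattern) and a TPC1b-like
  76-residue counterpart with basic/hydrophobic loops (zero matches, and
  no Asp anywhere, making the zero-hit property structural); the alignment
  carries the TPC1b gap at column 47, exercising the position map. Paired
  pseudo-structures are Cα-only: loop residues ring the two ion sites at
  4 Å, all other residues sit on a rail ≥ 7.5 Å away; ideal-helix backbone
  realism and side-chain rotamers are intentionally absent. The generators
  emulate occupancy statistics and composition contrasts, **not** force-
  field physics, water, correlated residue motion, or realistic loop
  geometry — passing tests validate the estimators and the pipeline
  arithmetic, not any claim about real channel trajectories.

## Configuration and pipeline

All analysis parameters are config defaults, not constants: cutoff 5 Å,
window last 500 ns at 0.1 ns, RMSD threshold 1 Å, per-replica durations
50 ns equilibration + 1000 ns production (so per_replica_total_ns = 1050
and three replicates analyze 1500 ns). Config validation is strict by
default (unknown keys rejected). The pipeline writes CSV tables, a Newick
tree and a JSON manifest; identical config + seed reproduces byte-identical
outputs. Logging goes to stderr, results only to files.

## Problem sizes

Tests and the acceptance script run at desk scale by design: random-
trajectory oracles use ≤10 atoms × ≤50 frames (exact agreement required);
parameter recovery uses 4000–10000 frames (3 binomial SE tolerance, KS
distance < 0.02 against the chi-3 radial law at 10⁴ near-independent
frames); the stability quantity uses 500 atoms × 5000 frames; the demo
pipeline runs three 500-ns-equivalent synthetic replicates in memory.

## Known limitations

No PBC unwrapping; no hydrogen-bond geometry (≤5 Å proximity is used as
the hydrogen-bonding likelihood proxy); no electrostatic energies or pKa;
no phylogenetics beyond UPGMA; published identity percentages from other
alignment tools are not expected to match to the digit because their
denominator conventions are unstated.
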