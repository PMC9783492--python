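# efca — EF-hand Ca²⁺ coordination analysis

`efca` is a Python package for characterizing Ca²⁺ coordination by EF-hand
domains of TPC1-type (two-pore, slow-vacuolar) channels, for structural
bioinformaticians comparing ordinary TPC1 channels with the degenerate
moss/liverwort TPC1b clade. It combines two tracks:

1. **Sequence track** — extract EF-hand domains from channel sequences
   (1-based inclusive `accession:start-end` spans), classify residues into
   Zappo-style chemical classes, compute pairwise percent identity and
   similarity from a multiple alignment, cluster domains with UPGMA, and
   scan for the canonical 12-residue EF-hand Ca²⁺-binding loop
   (`D-x-[DNS]-{ILVFYW}-[DENSTG]-[DENQGHRK]-{GP}-[LIVMC]-[DENQSTAGC]-x-x-[DE]`).
   An empty motif scan is a *result* (degenerate TPC1b-like loops), not an
   error.

2. **Trajectory track** — for MD trajectories stored as multi-model PDB
   (Ca²⁺ ions as HETATM records), compute Kabsch-superposed RMSD against
   the first frame, per-residue RMSF, and the core coordination statistic:
   the **contact frequency** of each residue,

   f(r) = #{sampled frames : min distance(heavy atoms of r, any Ca²⁺) ≤ c} / #frames,

   with cutoff c = 5 Å, sampled over the last 500 ns of each replicate at
   0.1 ns and pooled across replicates (3 × 500 ns = 1500 ns analyzed by
   default), plus the distribution of each residue's centre-of-mass
   distance to the nearest ion (residues with mean > 9 Å are flagged
   non-coordinating). A point-charge Coulomb score ranks binding-site
   electronegativity as a coarse surrogate for electrostatic surfaces.

Because production MD trajectories are rarely redistributable, the
`efca.synthetic` module generates trajectories with *known* ground truth —
an overdamped-Langevin ion in a harmonic well (stationary radius
chi-distributed, 3 d.o.f., scale σ = √(k_BT/k), so the occupancy
P(r ≤ c) is closed-form), an i.i.d. two-state bound/unbound ion with an
exact recorded bound count, Gaussian-noise trajectories with expected
RMSF = σ√3, and matched TPC1-like (acidic-loop) vs TPC1b-like
(basic/hydrophobic-loop) fixture sequences and pseudo-structures.

## Worked example

Estimate a harmonic-well ion's site occupancy and compare with the closed
form:

```python
import efca
from efca.synthetic import make_probe_system

top, coords = make_probe_system()                       # 1 residue + 1 Ca2+
cfg = efca.HarmonicIonConfig.from_sigma(2.5, n_frames=10_000, seed=1)
traj = efca.gen_harmonic_ion(cfg, top, coords)
table = efca.contact_frequency(traj, efca.AnalysisWindow(last_ns=1000.0, stride_ns=0.1))
print(f"closed form  P(r<=5A) = {efca.harmonic_occupancy(2.5, 5.0):.4f}")
print(f"estimated    f(res 1) = {table.frequency_of(1):.4f}  ({table.frames_counted} frames)")
```

```
closed form  P(r<=5A) = 0.7385
estimated    f(res 1) = 0.7339  (10000 frames)
```

The estimate sits within three binomial standard errors (≈0.013) of the
stationary-law prediction. The same estimator applied to replicate
trajectories of a real system produces `contacts.csv` /`distances.csv`
tables whose metadata records the pooled analysis time
(`n_replicates × last_ns`).

From the shell, the pipeline runs end to end on a bundled synthetic demo:

```bash
printf 'demo: true\noutput_dir: demo_out\n' > demo.yaml
efca run demo.yaml
python -c "import json; m=json.load(open('demo_out/manifest.json'));
print(m['n_replicates'], m['total_time_ns'], m['per_replica_total_ns'])"
# 3 1500.0 1050.0
```

Other entry points: `efca seq stats|scan|composition`,
`efca traj rmsd|rmsf|contacts|distances`, `efca synth harmonic|two-state|noise|fixtures`.

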