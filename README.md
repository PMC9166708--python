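# hjkit

Analysis toolkit for Holliday-junction (HJ) based DNA crystal design.

Self-assembling 3D DNA crystals are built around an immobile four-way
junction: four duplex arms meeting at a branch point whose sequence
asymmetry forbids branch migration, fixing the crossover in place. Which
of the possible branch-point sequences is used, how the two coaxially
stacked helices of the folded (stacked-X) junction cross, and whether
cations can bridge the crossover phosphates all decide whether — and in
which symmetry — a lattice assembles. `hjkit` implements the computations
a designer or simulator needs around these questions:

* **combinatorics** — an explicit strand-exchange model of one-step branch
  migration. Enumerating all 4⁴ = 256 Watson–Crick quartets at the branch
  point, discarding those mobile on either opposing-arm axis, and collapsing
  cyclic strand relabelings yields exactly **36 immobile junction classes**
  (144 immobile assignments in orbits of four).
* **geometry** — the signed interhelical angle *J*<sub>twist</sub>. Each
  stacked helix axis is fit by total least squares through the base-pair
  C1′ midpoints; the angle is the dot angle of the two oriented axes, and a
  reference vector across the branch point classifies handedness (dot angle
  with the axes' cross product, 90° threshold); left-handed angles are
  normalized by −1.
* **ions** — branch-point cation capture. Each crossover phosphate plus the
  acceptor atoms (N7/O6/O4/O2/N3) of the adjacent branch-point base pairs
  defines a bridging site (Pos1/Pos2); an ion within 3.6 Å of both a
  phosphate oxygen *and* a base acceptor of the same site is a bridging
  event, and the **incidence** is the fraction of trajectory frames with at
  least one event.
* **lattice** — idealized prism models of the crystal solvent cavities
  (triangular and hexagonal prisms) and per-axis statistics over unit cells.
* **synth** — a synthetic stacked-X generator producing structures and
  multi-model-PDB trajectories with machine-readable ground truth (true
  angle, handedness, bound-frame sets), so every analysis is validated
  against constructions whose answer is known exactly.
* **structure_io** — PDB/mmCIF reading (gemmi-backed), junction topology
  annotation from a small JSON spec, and a multi-model PDB trajectory
  dialect (`MODEL`/`ENDMDL` blocks with a constant atom list).

## Worked example

```python
from hjkit.combinatorics import enumerate_immobile_classes
from hjkit.geometry import jtwist
from hjkit.ions import incidence
from hjkit.synth import IonPlan, SynthSpec, build_junction, build_trajectory

classes = enumerate_immobile_classes()
print(len(classes))                     # 36

s, truth = build_junction(SynthSpec.from_quartet("AACC", angle=60.0,
                                                 handedness="left"))
print(jtwist(s).signed_angle)           # -60.00 (left-handed -> negative)

traj, _ = build_trajectory(SynthSpec.from_quartet(
    "AACC", n_frames=100, noise_sigma=0.3, seed=11,
    ion_plans=(IonPlan(frames=frozenset(range(53))),)))
print(incidence(traj).incidence)        # 0.53
```

The `examples/` directory holds one narrative script per capability;
`python examples/measure_jtwist.py` prints, e.g.:

```
built  +60.0 deg (right) -> recovered  +60.00 deg
built  -60.0 deg (left ) -> recovered  -60.00 deg
100 noisy frames at 55 deg: median 54.98, mean 54.98, sigma 0.25
```

i.e. the signed angle estimator recovers the constructed geometry exactly at
zero noise and stays unbiased under 0.3 Å atomic noise. Similarly
`examples/cavity_volumes.py` prints the idealized pore volumes of the two
lattice symmetries — 23.8 nm³ (triangular, 3 nm edge, 6.1 nm height) vs
638.5 nm³ (hexagonal, 6.4 nm edge, 6.0 nm height), a 26.9-fold difference.

A thin CLI wraps the same functions:

```bash
hjkit enumerate --fasta classes.fasta
hjkit synth --angle 60 --frames 100 --bound-frac 0.53 --seed 7 --out demo/
hjkit jtwist --structure demo/junction.pdb --spec demo/junction_spec.json
hjkit ions --structure demo/junction.pdb --spec demo/junction_spec.json \
           --traj demo/trajectory.pdb
hjkit cavity --kind hex --edge 6.4 --height 6.0
```

## Analyzing real structures

The readers accept standard PDB/mmCIF, so deposited junction structures and
multi-model PDB exports of MD trajectories can be analyzed directly: write a
junction spec JSON naming the four strand runs (chain, first/last residue,
crossover residue) and the two coaxially stacked arm pairs, then run
`hjkit jtwist` / `hjkit ions` as above, or `hjkit cellstats --pdb-dir DIR`
to group CRYST1 cells by space group. Which arms stack coaxially (the
stacking isomer) must be supplied by the user; no numeric equivalence with
other tools' junction-angle definitions is claimed.

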