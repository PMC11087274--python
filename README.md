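# nanoreax

Nanoreactor active-learning (NR–AL) sampling for reactive machine-learning
interatomic potentials, with MolFind-style reactive-trajectory analysis —
at desk scale.

Condensed-phase reactive chemistry (combustion, carbon-phase nucleation,
prebiotic synthesis) happens on timescales that quantum-mechanical MD
cannot reach. The NR–AL strategy builds a reactive machine-learning
interatomic potential (MLIP) automatically: *nanoreactor* MD simulations
drive small CHNO boxes through oscillating temperature and density
programs,

```
T(t) = T_start + (t/t_max)·(T_end − T_start) + T_amp·sin²(t/t_per)
ρ(t) = ρ_start + (t/t_max)·(ρ_end − ρ_start) + ρ_amp·sin²(t/t_per)
```

so that molecules collide and react; an M-member committee of potentials
watches its own disagreement (query by committee),

```
ε_E = std_members(E) / √N        ε_F = ⟨ ‖std_members(F_i)‖ ⟩_atoms
```

and the first configuration whose disagreement exceeds the selection
thresholds (1.85 kcal mol⁻¹ N^(−1/2) on energy, 6.92 kcal mol⁻¹ Å⁻¹ on
forces) ends the simulation and is sent to the reference labeler. Labeled
structures accumulate, the committee retrains, and simulations survive
longer and longer — the campaign converges when they routinely run to full
length.

`nanoreax` implements this whole loop as a tested, single-CPU package: the
periodic-geometry core, the system builders (random carbon boxes, packed
seed-molecule mixtures), the schedule generator, a BAOAB Langevin MD
engine, Behler–Parrinello-style symmetry-function descriptors with
analytic gradients, a trainable committee of per-element regressors, the
active-learning driver, and **MolFind**: bond-graph species census
(graph-isomorphism canonical keys), ring census (minimum cycle basis),
species tracking and the ignition-delay-time statistic. A built-in *toy
reactive potential* (pairwise Morse with smooth cutoff, bonds form and
break freely) stands in as the labeler so the entire workflow runs on a
laptop; a file-exchange adapter documents how to plug in a DFT engine.

## Worked example

Build the methane-combustion starting box (20 CH4 + 40 O2 at 0.25 g/cc),
run short toy-potential MD, and analyze the trajectory:

```bash
$ nanoreax build --system methane --seed 1 --out methane.extxyz
[nanoreax 0.1.0] build --system methane --seed 1
[nanoreax 0.1.0] wrote 180 atoms at 0.2500 g/cc to methane.extxyz

$ nanoreax analyze --traj methane.extxyz --species
[nanoreax 0.1.0] analyze methane.extxyz: 1 frames, 180 atoms
formula                      key  first_frame  last_frame  max_count
    CH4 wl1:CH4:c73b56c28798fa11            0           0         20
     O2  wl1:O2:995febc043fef1a6            0           0         40
```

The census confirms the packed box contains exactly the 20 methane and 40
oxygen molecules it was built from — species are counted by bond-graph
topology (C–C contacts closer than 1.72 Å are bonded, and so on), not by
bookkeeping. A desk-scale active-learning campaign runs the same way:

```bash
$ nanoreax al-run --generations 4 --seed 2 --out-dir run/
$ nanoreax predict --model run/ensemble.json --in methane.extxyz
```

`run/history.tsv` records, per generation, the number of uncertainty flags,
the dataset size and the mean simulation time before a flag — the quantity
whose growth is the campaign's learning signal.

From Python, the same loop is three calls:

```python
import numpy as np
from nanoreax.active_learning import ALConfig, run_until_converged
from nanoreax.potentials import ToyReactivePotential

state = run_until_converged(
    None, ALConfig(seed=0), ToyReactivePotential(),
    np.random.default_rng(0), max_generations=6,
)
print([r.mean_sim_time_fs for r in state.history])
```

## Layout

```
src/nanoreax/
  system.py           periodic cells, minimum-image geometry, neighbor search
  builders.py         seed molecules, carbon boxes, molecule packing
  schedules.py        oscillating T/ρ programs and random draws
  md.py               BAOAB Langevin dynamics + nanoreactor driver
  potentials.py       calculator contract, toy reactive potential, labeling
  descriptors.py      radial/angular symmetry functions, analytic gradients
  ensemble.py         committee model, QBC uncertainty, training
  active_learning.py  bootstrap → sample → select → label → train loop
  molfind.py          bond graphs, species/ring census, tracking, IDT
  extxyz.py           extended-XYZ reader/writer
  archive.py          versioned JSON dataset/model archives
  labeler_adapter.py  file-exchange protocol for external (DFT) labelers
  cli.py              nanoreax build | simulate | predict | al-run | analyze
```

See `docs/methods.md` for the scientific choices, defaults and limitations.
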