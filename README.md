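# actinwaves

A continuum simulator of dendritic actin waves on the substrate-attached
membrane of PTEN-deficient *Dictyostelium discoideum*, together with a
discrete monomer-resolved model used as a verification oracle.

## The problem

Cells recovering from actin depolymerization (and PTEN-null mutants in
particular) display travelling waves of branched F-actin on their ventral
surface: closed bands a few micrometres tall that expand at roughly
0.1 µm/s, enclose a region of elevated PIP3/Rac activity, annihilate on
collision, and stall or retract where PTEN is active. This package
implements a mechanistic model of those waves for people studying
cytoskeletal pattern formation: the filament network is resolved along the
vertical axis while the signalling layer that drives branching is condensed
into a single diffusible switch (Rac).

## The model

On a vertical cross-section (x, z) of the cell, with the membrane at z = 0:

* **Filaments** grow vertically, tethered at their barbed ends to the
  membrane, and are represented by pointed-end densities of three types:
  free (*p*), Arp2/3-capped (*r*), coronin-capped (*c*). Capped filaments
  advect upward at the polymerization speed `v_poly·g_m`; free filaments
  advect at `v_poly·g_m − v_depoly`. Coronin binding converts *r* → *c*
  (releasing Arp2/3); debranching converts *c* → *p* (releasing coronin);
  free pointed ends depolymerize, feeding G-actin back to the cytosol.
* **Diffusible species** — G-actin (*g*), Arp2/3 (*arp*), coronin (*cor*),
  inactive/active Rac (*rac*, *rac\**) — obey reaction–diffusion equations
  with flux boundary conditions at the membrane and no-flux walls.
* **Membrane layer** (per x, non-diffusing): membrane-bound G-actin `g_m`,
  the WASP cycle W → W\* → W·Arp2/3 → W·Arp2/3·G-actin (the branching
  complex), and short filaments of length ≤ 2 whose kinetics differ from
  the continuum. A pseudo-steady length-3 pool supplies the z = 0 boundary
  flux of the continuum fields.
* **Positive feedback**: barbed ends activate Rac
  (`k_rac_act·B·rac`), activated Rac activates WASP, loaded WASP complexes
  nucleate new branches on existing barbed ends (`k_branch·WAG·B`). A PTEN
  surrogate region simply disables the barbed-end-driven Rac activation.

Waves are initiated by a precursor: a transient local fold-increase of the
dimerization rate constant. Four global budgets (actin, Arp2/3, coronin,
Rac) are conserved exactly by construction; a discrete model that tracks
filaments per subunit length verifies the continuum reduction.

## Worked example

```python
import numpy as np
import actinwaves as aw
from actinwaves.observables import observable_series, track_fronts

cfg = aw.scenario("single_precursor")   # 20 x 3 um cross-section, 150 s
traj = aw.run(cfg)
ser = observable_series(traj, species=("factin", "rac_star"))
fronts = track_fronts(traj.times, ser.tirf["factin"], cfg.grid)
sel = (fronts["right"].positions > 14) & (fronts["right"].positions < 18)
print("front speed  %.3f um/s" % np.nanmedian(fronts["right"].speeds[sel]))
print("TIRF peak    %.2f uM*um" % np.nanmax(fronts["right"].peak_heights))
```

prints

```
front speed  0.093 um/s
TIRF peak    6.52 uM*um
```

— a stimulated spot ignites, splits into two fronts that travel outward at
just under 0.1 µm/s (the experimentally observed speed scale), with an
F-actin TIRF intensity of ≈ 6.5 µM·µm (≈ 33 µM F-actin within the 0.2 µm
TIRF depth) at the front and activated Rac confined to the enclosed region.

The same can be run from a shell:

```
actinwaves scenario single_precursor -o run.yaml
actinwaves run run.yaml -o trajectory.h5
actinwaves audit trajectory.h5
actinwaves observables trajectory.h5 -o observables.csv
```

Canned scenarios: `single_precursor`, `collision`, `feedback_off`,
`coronin_off`, `coronin_off_low_debranch`, `pten_block`, `pten_moving`,
`pten_split`, `high_arp_membrane_diffusion`. Configurations are YAML files;
every key of `ModelParams` (units documented in its docstring: µM, µm, s;
surface densities in µM·µm) and `GridSpec` may be overridden.

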