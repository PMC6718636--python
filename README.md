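# protustim

Field modeling and in vivo data analysis for **protuberant ("mushroom")
subretinal microelectrodes** — 3D wells with electroplated pillar electrodes
and a surrounding ground grid, a geometry proposed to bring the stimulating
metal closer to surviving retinal bipolar cells and to confine the stimulus
current inside each cavity.

The package is aimed at neural-interface modelers and experimentalists who
want to reproduce, on synthetic data, the three quantitative stages of such a
device study:

1. **Volume-conductor field simulation.** The potential in the physiological
   liquid obeys the DC conduction equation ∇·(σ∇V) = 0 with insulating
   boundaries ∇V·**n** = 0 at substrate surfaces and a mixed
   electrode–electrolyte condition σ∇V·**n** = g (V_metal − V) at metal
   surfaces (ideal Dirichlet limit available).  A cell-centered finite-volume
   scheme on a uniform voxel grid is solved by preconditioned conjugate
   gradients; the derived current density **J** = −σ∇V and the
   activating-function proxy ∂²V/∂x_i² quantify where stimulation is
   expected to act.  Three geometries are compared under identical
   parameters: a flat electrode in a well (G0), one mushroom (G1), two
   mushrooms (G2).
2. **Histology composition statistics.** Per-cavity counts of bipolar, glial
   and other cells are normalized to percentages within each cavity and
   summarized as unweighted means ± sample SD by cavity width (60/80/100 µm)
   and by protuberance count (0–4).
3. **Evoked-potential analysis.** Charge-balanced symmetric biphasic
   stimulation waveforms (1 ms phases, 1 ms gap, three repeats); cortical
   recordings sampled at 25 kHz are band-pass filtered 1–100 Hz (zero-phase),
   averaged over 100 trigger-aligned trials, and characterized by evoked
   amplitude and latency across the 64–256 µA stimulation series.

No raw in vivo data are deposited with the study, so stages 2–3 run on
calibrated synthetic generators (multinomial cavity compositions and a
sigmoid-response evoked-LFP model) bundled as first-class, tested modules.

## Worked example

Compare the three electrode geometries of the reference 100/80/12
configuration (100 µm hexagonal well, 80 µm electrode disc, 12 µm pillar
stems) at 2 µm voxels with 1 V applied and ideal electrode interfaces:

```python
from protustim import StructureConfig, compare_geometries

report = compare_geometries(StructureConfig(100, 80, 12))
for name, g in sorted(report.geometries.items()):
    print(f"{name}: line C peaks at {[round(p, 1) for p in g.peak_positions['C']]} um, "
          f"peak |J| C/B/A = {g.central_peak_jmag['C']:.0f}/{g.central_peak_jmag['B']:.0f}/"
          f"{g.central_peak_jmag['A']:.1f} A/m2, "
          f"max |d2V/dz2| central = {g.max_d2v_dz2_central:.2e} V/m2, "
          f"I_stim = {g.stim_current_A * 1e6:.2f} uA")
```

prints:

```
G0: line C peaks at [-35.0, 35.0] um, peak |J| C/B/A = 388/275/1.3 A/m2, max |d2V/dz2| central = 7.84e+08 V/m2, I_stim = 2.78 uA
G1: line C peaks at [-35.0, -1.0, 35.0] um, peak |J| C/B/A = 433/277/1.4 A/m2, max |d2V/dz2| central = 1.05e+10 V/m2, I_stim = 2.81 uA
G2: line C peaks at [-25.0, 25.0] um, peak |J| C/B/A = 506/286/1.4 A/m2, max |d2V/dz2| central = 1.32e+10 V/m2, I_stim = 2.84 uA
```

Reading these numbers: on the sampling line inside the cavity (line C) the
flat electrode G0 shows only its two **edge peaks** near ±40 µm; the single
mushroom adds one peak on the pillar axis (0 µm) and the double mushroom
produces two peaks over its pillar caps (axes at ±20 µm).  The peak current
density over the electrode attenuates with distance from the electrode plane
(line C → B → A), and the maximum axial second derivative of the potential
in the central cavity zone — the activating-function proxy — is an order of
magnitude larger with mushrooms than without: the pillars concentrate the
field variation exactly where in-migrated bipolar cells would sit.

The same comparison is available from the shell, with VTK/CSV/JSON exports
and a run manifest:

```sh
protustim compare-geometries --code 100/80/12 --spacing 2 --out runs/cmp
protustim make-synthetic --stage histology --grouping width --seed 1 --out runs/gen
protustim histology-summarize --input runs/gen/cavities.csv --out runs/hist
```

## Layout

- `src/protustim/geometry.py` — voxel geometries (wells, mushrooms, ground grid)
- `src/protustim/solver.py` — finite-volume DC conduction solver
- `src/protustim/field_analysis.py` — line profiles, peaks, activating-function maps
- `src/protustim/histology.py` — cavity composition statistics
- `src/protustim/ephys.py` — stimulation waveforms and evoked potentials
- `src/protustim/synthetic.py` — calibrated synthetic-data generators
- `src/protustim/cli.py` — pipeline driver (`protustim` command)
- `docs/methods.md` — model, assumptions, parameter choices, limitations
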