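# patchrig

A virtual rig for **image-guided robotic whole-cell patch clamp**.

Obtaining an in vivo whole-cell recording from a *specific*, fluorescently
labelled neuron requires guiding a glass micropipette to a soma a hundred
micrometres deep under two-photon imaging. Automating this is hard for one
central reason: pushing a pipette into soft brain tissue viscoelastically
deforms it, so the target cell migrates away from its stored location while
the very shallow two-photon depth of field makes it vanish from view a few
micrometres off the focal plane. The robotic solution is a closed visual
servo loop — segment the image, score each object's focus, keep the target
in focus by sweeping the objective, and interleave every small insertion
step with re-detection of the target before the next step is allowed —
followed by an electrophysiological state machine (engagement, gigaseal
formation under adaptive suction, break-in by suction pulses).

`patchrig` implements that entire control stack as a tested software
package, exercised against a built-in virtual preparation: synthetic
two-photon frames of fluorescent somata and a dye-filled pipette cone,
a viscoelastic tissue-deformation model, breathing/heartbeat motion, a
first-order pneumatic plant under PID control, and a pipette/membrane
impedance simulator. No microscope, manipulator, or animal is involved;
every run is a deterministic, seeded simulation.

## The core quantities

**Contrast-focus score (CFS).** For each segmented object *i*,

```
CFS_i = (<I>_internal,i - <I>_external,i) / <I>_internal,i
```

where `<I>_x` averages pixel intensity over the eroded interior of the
particle (`internal`) and over the ring between the original and eroded
boundaries (`external`). The CFS is scale-invariant and peaks when the
object is in focus; the autofocus loop sweeps the focal plane and takes
the maximum of a Gaussian fitted to CFS-versus-z.

**Step-size bound.** Insertion steps are limited to 3–4 µm so that the
tissue migration induced by a single step never exceeds half the diameter
of the smallest targeted somata (≈5–8 µm) — which is exactly the local
search gate of the tracker, so the correspondence problem stays local.

**Seal-test resistance.** A 10 mV, 10 Hz square wave is applied; the
current is sampled at 20 kHz, Bessel low-pass filtered, and the pipette
resistance computed per cycle as `R = V / I_peak-to-peak` (10 mV / 2 nA =
5 MΩ in the bath; 10 mV / 10 pA = 1 GΩ at seal). Pressure is staged with
distance (high 10–50 kPa far away, 5–10 kPa within 20 µm, released at
contact), and suction is deepened adaptively during sealing only when R is
below 15 % of the seal threshold *and* has risen less than `S_th` over the
window `T_seal`.

## Worked example

```python
import patchrig

result = patchrig.run_experiment(patchrig.default_config(seed=1))
print(result.status)                  # wholecell
print(result.steps)                   # 73
print(result.log.stage_sequence())
# ['positioning', 'approach', 'engagement', 'seal', 'breakin', 'wholecell']
print(round(result.time_to_seal, 1))  # 2.4  (simulated seconds of sealing)
print(round(max(result.tracked_errors), 2))  # 1.89  (um, always < the 3.5 um gate)
```

The run descends ~250 µm from the standoff point in 3.5 µm steps, each
followed by target reacquisition (with autofocus sweeps when the target's
CFS collapses), reduces pressure at the 20 µm boundary, detects engagement
by the impedance rise, seals under −70 mV holding with adaptive suction,
and breaks in with escalating suction pulses. `result.traces` holds the
time course of resistance, current, holding potential, internal pressure,
and depth; `result.trajectory` the per-step tip path.

A command-line interface is included:

```sh
patchrig simulate --seed 1 --frames 10 --out stack.tif   # render a stack
patchrig track stack.tif --out objects.csv               # vision only
patchrig patch --seed 1 --out-dir run1                   # full experiment
patchrig report run1                                     # summary + plot
```

## Layout

| module | role |
| --- | --- |
| `patchrig.scene` | virtual preparation: cells, pipette cone, deformation, physiological motion, 16-bit two-channel rendering, TIFF stack I/O |
| `patchrig.vision` | channel separation, background correction, Otsu segmentation, hole filling, erosion, particle analysis, CFS |
| `patchrig.autofocus` | focal sweeps and the Gaussian peak fit |
| `patchrig.tracking` | gated nearest-neighbour correspondence, occlusion tolerance, step-synchronized reacquisition |
| `patchrig.servo` | entry planning, interleaved step-and-reacquire approach, pressure staging |
| `patchrig.pneumatics` | PID controller with anti-windup driving a saturating first-order plant |
| `patchrig.ephys` | seal-test synthesis, Bessel filtering, resistance estimation, impedance simulator, adaptive suction, seal/break-in detection |
| `patchrig.rig` | orchestration, event logs, batch runs |
| `patchrig.cli` | `simulate` / `patch` / `track` / `report` subcommands |

See `docs/methods.md` for the models, parameter choices, and limitations.
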