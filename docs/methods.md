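# Methods

This note documents the models behind `patchrig`, the defaults and why
they were chosen, what the virtual preparation does and does not emulate,
and the numerical choices that matter for reproducibility.

## Virtual preparation (`patchrig.scene`)

**Geometry.** Volume coordinates are micrometres in a right-handed frame
with z = 0 at the pial surface and z negative going deeper. The default
scene places one 10 µm target soma near (0, 0, −120) µm with three
distractor somata 25–40 µm away (positions jittered ±4 µm per seed), a
field of view of 100 × 100 µm at 128 × 128 pixels, and a pipette entering
at ≈35° pitch. Frames are two 16-bit channels (red, green) matching the
two PMT/filter paths of a two-photon rig; the nominally RGB stream's blue
plane carries no signal and is not modelled.

**Cell rendering.** A soma of radius R at axial offset Δz from the focal
plane contributes a radially symmetric blob

```
I(r) = A · E(Δz) · C(σ) · ½(1 − erf((r − R)/(σ√2)))
E(Δz) = exp(−Δz² / (2 σ_vis²))        axial visibility envelope
σ     = σ₀ + ρ·|Δz|                    lateral blur
C(σ)  = (1 − e^{−R²/2σ²}) / (1 − e^{−R²/2σ₀²})   core erosion, normalized
```

so the in-focus centre carries exactly `peak_intensity`, the edge is the
erf profile of a disk convolved with a Gaussian, and the core amplitude
erodes once the blur approaches the soma radius. Defaults: σ₀ = 2 µm,
ρ = 0.1 µm/µm, σ_vis = 2.5 µm. These were chosen so that (a) an object a
few micrometres off the focal plane effectively disappears (the shallow
two-photon depth of field that motivates the autofocus loop), and (b) the
contrast-focus score of a rendered soma is strictly maximal at the soma's
own plane: with near-constant lateral blur, the score is a monotone
function of the visibility envelope against the background level, which
is the regime in which a ratio-form contrast score works as a focus
metric. A uniform neuropil/autofluorescence background (default 2 000–
5 000 counts with a gentle linear gradient across the field — the
"non-uniform lighting" the background-correction stage removes) is part
of image formation; with the background parameter set to zero an empty
scene renders an all-zero frame.

**Pipette.** The dye-filled pipette is a cone (tip diameter 1 µm, half
angle 10°) rendered as its exact intersection with the focal plane at
full dye intensity — the part of a steep cone crossing the plane is in
focus by construction — plus a tip glow subject to the same defocus law
as cells. The dye channel (red by default) differs from the target
channel, so cell segmentation is unaffected by the approaching shank.

**Tissue deformation.** The mechanics of pipette insertion are reduced to
a two-parameter push with partial recoil: a step `s` of the tip displaces
a cell at distance r from the pre-step tip position by
`g·exp(−r/λ)·s` (gain g = 0.5, decay length λ = 30 µm); a fraction
(default 0.5) of each displacement decays back toward rest with time
constant 5 s. With a 3.5 µm step the worst-case single-step migration is
1.75 µm, and cumulative migration near the tip reaches several
micrometres per few steps — enough that the tracker must compensate, and
calibrated so a single step can migrate a nearby target by up to about
half a small soma diameter. Real tissue rheology (layer, age, temperature
dependence) is explicitly not modelled; the functional form is a design
choice, not a measurement.

**Physiological motion.** Breathing (0.8 µm at 2.5 Hz) and heartbeat
(0.25 µm at 8 Hz) are zero-mean sinusoids along a mostly axial axis —
they make the target periodically defocus and reappear at the same
place, which is what the occlusion tolerance of the tracker absorbs.

**Noise.** Shot noise uses an exact Poisson draw below ~1000 expected
photons and a Gaussian approximation (variance ∝ signal) above, plus
Gaussian read noise (σ = 60 counts). All randomness derives from the
scene seed.

**Stack I/O.** Multi-page 16-bit TIFF, two pages per frame (red then
green); per-frame metadata (focal z, timestamp, stage offset) as JSON in
the red page's ImageDescription tag. Round trips are lossless.

## Vision (`patchrig.vision`)

Pipeline order: channel selection (red, green, or saturating sum) →
background correction → Otsu thresholding → hole filling → particle
analysis with per-object erosion → CFS.

- **Background correction** subtracts a large-window (48 px) local median
  computed on a block-reduced copy and bilinearly resized back, floored
  at zero and re-quantized to 16 bits. Full-resolution median filtering
  at this window would dominate the per-frame budget; the block-reduced
  estimate is indistinguishable for backgrounds smooth on the window
  scale. A constant image maps to all zeros.
- **Otsu** is computed on the observed histogram by maximizing the
  between-class variance with a fast float64 scan refined by exact
  integer arithmetic among near-tied candidates; ties break toward the
  lowest threshold. This makes the threshold the *exact* exhaustive
  maximizer, testable against a brute-force oracle. A constant image is
  degenerate (no threshold, empty mask). If the resulting mask covers
  more than 20 % of the frame the cut sits inside the noise floor
  (percolating speckle) and the frame is treated as containing no
  objects.
- **Particle analysis** labels 8-connected components (holes are filled
  with 4-connected background, the standard dual), filters areas outside
  [20, 1200] px, renumbers labels in raster order, and records contour,
  area, bounding box, and the *binary* centre of mass (segments are
  binary after thresholding). The internal mask is the component eroded
  by a 2 px disk; the external ring is the remainder. A 2 px ring is thin
  enough to sample the object's rim yet ≥1 px everywhere for the cells
  modelled here; both radius and area bounds are configuration.
- **CFS** is evaluated on the original (uncorrected) channel image
  through the masks; interior mean of zero (or an empty region) yields a
  NaN sentinel and the object is unusable for focus. The score is exactly
  invariant under positive scaling of the image.

## Autofocus (`patchrig.autofocus`)

A centred bidirectional sweep (default half-range 10 µm, step 2 µm)
acquires one frame per plane, segments, matches the object nearest the
region of interest, and records its CFS (0 when absent). A Gaussian
`a·exp(−(z−µ)²/2w²) + c` is least-squares fitted to the scores in
z-centred coordinates (making the fit translation-equivariant);
initialization is amplitude = range, peak = argmax, width = 2·step,
offset = min. Only samples above 15 % of the score range enter the fit —
the far tails of the focus curve are governed by detection cutoffs, not
by the Gaussian core, and would bias the peak. The fit is rejected
(fallback: argmax sample, never outside the sweep) if the peak leaves the
sweep range, the width collapses below the step, or the residual norm
exceeds half the score range; fewer than 4 non-zero scores sets a
low-confidence flag. A lost sweep is retried once with the half-range
doubled before loss is reported.

## Tracking (`patchrig.tracking`)

Gated nearest-neighbour association with no motion model: the detection
nearest the track's last (x, y) within the search radius wins (ties by
larger CFS, then lower label). The search radius defaults to half the
smallest targeted soma diameter (3.5 µm for 7 µm) — the same bound the
step-size rule enforces on per-step migration, which is why
constant-position gating suffices. Misses increment an occlusion counter
(budget 5 frames, sized to outlast a breathing cycle at the 0.25 s frame
period) before the target is declared lost. After every insertion step
the target must be reacquired before the next step; a lateral miss, or a
match whose CFS has fallen below 0.65 of the acquisition reference
(axial migration), triggers an autofocus sweep first.

## Servo (`patchrig.servo`)

Entry planning aligns the pipette axis through the target and places the
tip at a standoff 250 µm away (band 200–300 µm); rapid moves are only
made outside tissue or along the aligned axis, and axis pitches outside
10–80° are planning errors. The approach loop then: stages pressure by
distance (25 kPa beyond 20 µm, 7 kPa at or inside it — the boundary maps
to the low value, the safer choice for the cell), takes one re-aimed step
of `min(3.5 µm, remaining)` whose direction passes through the updated
target position (per-step lateral correction bounded; re-aiming is
per-step 3D correction, the minimal faithful reading of continuous
trajectory adjustment), applies the tissue deformation, and requires
reacquisition before the next step. The loop terminates at a tip-to-track
distance ≤ 5 µm (≈ cell radius); one final bounded correction (< 8 µm)
closes any residual gap and is flagged distinctly in the log, making the
simulated pipeline fully autonomous. A step budget of 3× the
no-deformation step count bounds runaway loops.

## Pneumatics (`patchrig.pneumatics`)

The valve network (two proportional valves, Venturi ejector, 3-port
selector) is collapsed into a signed first-order plant: the controller
output is a valve drive u ∈ [−100, 100] %, with equilibrium pressure
`(u/100)·supply` on the positive branch and `(u/100)·|vacuum limit|`
(−80 kPa) on the vacuum branch, time constant 0.1 s, integrated with the
exact exponential step (so the one-τ 63.2 % property holds for any dt)
and clipped to [vacuum limit, supply]. Because the plant gain scales with
the supply, supply fluctuations genuinely disturb the loop and are
rejected by feedback — the practical argument for closed- over open-loop
pressure control. The PID (kp = 6, ki = 60 s⁻¹, kd = 0, 1 ms sample time,
derivative on measurement to avoid setpoint kick, clamped integral and
output) was tuned for overdamped settling in ≲0.3 s at τ = 0.1 s; gains
are configuration.

## Electrophysiology (`patchrig.ephys`)

Units are mV / nA / MΩ / kPa / s throughout (10 mV / 2 nA = 5 MΩ).

- **Seal test:** 10 mV square wave at 10 Hz on an optional −70 mV
  holding level, sampled at 20 kHz. The digital low-pass is a 4th-order
  Bessel at 9 kHz — the closest realizable digital stand-in for the
  amplifier's 10 kHz analog filter, since a digital cutoff must lie below
  the 10 kHz Nyquist frequency of the 20 kHz stream.
- **Resistance:** per cycle, R = amplitude / peak-to-peak current, with
  the peak-to-peak measured as the difference of the 97.5th and 2.5th
  percentile (the plateau levels of the square response — exact for an
  ideal resistor, robust to filter edge transients); the median across
  cycles is reported (median rather than mean, for robustness). Currents
  below a 0.1 pA floor give an "unmeasurable" sentinel.
- **Impedance simulator:** stage-dependent R(t). Bath: constant 6 MΩ
  (band 5–7). Contact: first-order rise by a factor 1.5. Sealing:
  logistic growth toward 1.8 GΩ with rate
  `k·(1 + 0.15·|P_suction|)·(1 + |V_hold|/70 mV)` advanced in closed form
  — the manoeuvre (gentle suction and hyperpolarization speed up seal
  formation) is what is modelled, not membrane biophysics; k is drawn
  lognormally per run (median 0.35 s⁻¹, σ = 0.5) so slow sealers exercise
  the adaptive-suction rule. Whole-cell: access resistance 16 MΩ.
  Break-in is triggered when the accumulated suction-pulse impulse
  (|kPa|·s) crosses a per-run lognormal threshold (median 6, σ = 0.4).
- **Detectors:** engagement = R sustained ≥ 20 % above its pre-approach
  baseline for 3 consecutive measurements; seal = R ≥ threshold (default
  1 GΩ, user band 1–1.5 GΩ); break-in = ≥10× drop within a short window;
  clogged = R ≥ 1.5× bath baseline away from the target (boundary
  inclusive).
- **Adaptive suction:** evaluated every 0.5 s during sealing; suction
  deepens by 1 kPa (bounded at −12 kPa) iff R < 15 % of the seal
  threshold *and* R rose by less than S_th = 5 MΩ over T_seal = 2 s.
  S_th, T_seal, and the step are stated as configuration with these
  defaults; the 15 % fraction and the seal time limit (30 s) are part of
  the procedure's definition. Hyperpolarization is applied as a step
  (a ramp mode exists behind configuration).

## Orchestration (`patchrig.rig`)

All timing is a simulated clock (0.25 s per acquired frame, 0.1 s per
resistance measurement); nothing depends on wall time, so identical
(config, seed) yields bitwise-identical event logs. A run proceeds
positioning → approach → engagement → seal → break-in → whole-cell, and
any failure terminates with a machine-readable reason (`no_target`,
`clogged`, `lost_target`, `engagement_failed`, `seal_timeout`,
`breakin_budget`). During the approach the tracker is refocused
periodically (every 6 steps, every 3 inside 40 µm where the per-step push
is largest) in addition to the CFS-drop trigger. Blind mode descends
along an aligned line watching only the impedance, reusing the engagement
detector; manual-assist mode is the targeted pipeline with stepwise
prompts and is excluded from batch statistics. Event logs are append-only
JSON lines with monotone timestamps and exactly one terminal event;
traces export with columns (time, resistance, current, holding, pressure,
depth).

Seeds: the run seed feeds a `SeedSequence` that spawns independent
streams for scene noise and for the electrophysiological heterogeneity;
batch seeds are derived as `base·100003 + i (mod 2³¹−1)`.

## Problem sizes

The default regression batch is 50 seeded runs (~73 insertion steps
each, ≈3 s wall time per run); the Otsu oracle check uses 100 random
small images; autofocus recovery uses one rendered noise-free sweep plus
200 synthetic noisy sweeps. These sizes make the full suite and the
acceptance script each complete in a few minutes on one CPU.

## What passing tests do and do not show

The virtual preparation reproduces the *control-relevant* phenomenology:
defocus-driven disappearance, insertion-induced target migration within
the designed bound, periodic physiological occlusion, pressure dynamics,
and impedance staging. It does not emulate optical scattering or
depth-dependent SNR loss, dye ejection accumulating in the tissue,
pipette clogging statistics, real tissue rheology, or membrane
biophysics — the seal/break-in dynamics are phenomenological. Batch
success rates over this simulator are therefore regression properties of
the software, not predictions of in vivo yield; the in vivo performance
of such a system can only be established at the bench.

## Known limitations

- Single target, single pipette; no multi-manipulator parallelism.
- Constant-position gating would break if frame periods were long enough
  for migration to exceed the gate between reacquisitions.
- The CFS is computed on the configured channel only; per-plane scores
  for RGB streams are not combined.
- The Otsu exact-refinement path scans unique intensity values and is
  sized for 16-bit microscopy frames, not arbitrary-depth data.
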