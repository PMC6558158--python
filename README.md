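# headgait

Head-stabilization metrics from dual body-worn IMUs during free-living
gait.

During walking, the upper body actively attenuates trunk motion so that
the head — carrying the visual and vestibular sensors — stays stable.
That attenuation degrades with age and in disorders such as Parkinson's
disease, multiple sclerosis and vestibular loss, which makes head
stability a candidate digital biomarker. Measuring it outside the
laboratory ("ecological momentary assessment") takes nothing more than
two inertial measurement units — one in a cap, one on a belt — worn
through an ordinary day. `headgait` is the full analysis chain for such
recordings, aimed at movement scientists and clinical researchers
working with wearable inertial data.

## What it computes

From two synchronized tri-axial IMU recordings (specific force in g,
angular velocity in rad/s, 100 Hz) the pipeline runs:

1. **Synchronization** — knock events (large synchronous spikes) at the
   start and end of the recording fit a linear clock model
   t_head = offset + (1 + drift)·t_trunk.
2. **Calibration** — a static posture and five pitch nods rotate each
   sensor into a body-fixed frame (x forward, y left, z up).
3. **Gravity filter** — a per-sample complementary filter propagates the
   gravity estimate through the gyroscope increment and blends it with
   the low-passed accelerometer, g ← α·g + (1−α)·a; the orientation
   quaternion q(t) is the tilt-only rotation taking g(t) onto the world
   vertical (never any yaw). Net inertial acceleration in the aligned
   frame is i_A = rot(q, a − g), with axes (AP, ML, V).
4. **Segmentation** — steps are peaks of vertical trunk acceleration
   (height ≥ 0.2 g, prominence ≥ 0.4 g, separation ≥ 0.2 s); cycling-like
   periods are excluded (low vertical RMS or mismatched V/ML predominant
   frequencies); steps group into bouts at < 1 s spacing; analysis is
   gated to head predominant frequencies in [1, 2.6] Hz.
5. **Per-step stability measures**
   * attenuation coefficient `AC = 1 − A_H/A_T` (head vs. trunk RMS);
   * harmonic ratio `HR = Σₖ S(k·f_dom) / Σₖ S((2k−1)·f_dom/2)` over
     N = 10 harmonics of the stride base f_dom/2 (inverted for ML);
   * Welch coherence `K² = |S_xy|²/(S_xx·S_yy)` at the predominant
     frequency, between head pitch velocity and vertical head
     acceleration, and between head and trunk pitch velocity;
   * cross-correlation phase difference with the −π/2 correction that
     maps acceleration-vs-velocity phase onto displacement-vs-angle
     phase.
6. **Summaries** — boxplot statistics per predominant-frequency bin and
   Kruskal–Wallis effect sizes η² = (H − k + 1)/(n − k).

Because no public recordings exist for this protocol, the package ships
a first-class synthetic generator (`headgait.synth`) producing
ground-truthed dual-IMU sessions — harmonic gait waveforms with
controlled attenuation, phase-locked head pitch, bout/rest structure,
cycling confounders, calibration postures, knocks, clock drift and
sensor noise — against which every stage is tested.

## Worked example

```python
import numpy as np
import headgait as hg

params = hg.GaitGeneratorParams(seed=1).noiseless()
head, trunk, truth = hg.generate_session(params, duration=600.0)
result = hg.run_session(head, trunk)

df = result.steps
print(result.counts["steps_retained"], len(truth.true_step_times))
for ax, target in zip(("AP", "ML", "V"), params.ac_targets):
    print(ax, round(df[f"ac_{ax}"].median(), 3), target)
print(round(np.rad2deg(df["phase_hv_hp"].median()), 1))
```

prints (from `examples/03_full_pipeline.py`):

```
candidate peaks 860, cycling excluded 34, retained 826 (truth: 826 steps)
sync: offset 0.3000 s (true 0.3), drift 9.67e-06 (true 1e-05)
AC AP: median 0.300  (target 0.3)
AC ML: median 0.198  (target 0.2)
AC V: median 0.050  (target 0.05)
phase head-V vs head-pitch: -50.2 deg (target -50)
coherence head-pitch vs head-V: 1.000
```

Reading: all 826 planted steps were found and none of the 34 cycling
spikes survived; the clock model was recovered to microseconds of drift;
the per-axis attenuation coefficients and the −50° head-pitch phase
planted by the generator come back through the *entire* chain (sync →
calibration → gravity filter → segmentation → measures) within ~0.002
and ~0.2° respectively; and the phase-locked pitch/acceleration coupling
yields coherence 1.

More narrative scripts live in `examples/` (generator tour, gravity-
filter validation, frequency-binned summaries and effect sizes). A thin
CLI wraps the same pipeline:

```
headgait simulate --duration 600 --seed 1 --out session/
headgait run --head session/head.csv --trunk session/trunk.csv --out results/
headgait summarize --steps results/steps.csv --out summaries/
```

## Layout

```
src/headgait/      io, orientation, spectral, segmentation, stability,
                   summary, synth, pipeline, cli
tests/             unit, property and acceptance tests (pytest)
examples/          narrative scripts, one per capability
docs/methods.md    models, assumptions, parameter rationale, limitations
```
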