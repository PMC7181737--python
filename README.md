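# strokekin

Kinematic analysis of pen movements for motor-learning experiments, in
two flavours:

* **Drawing (target) task** — a stylus connects four printed targets in
  a fixed order (A>B>C>D>A) as rapidly and accurately as possible.
  Skilled movers *coarticulate*: they blend consecutive strokes instead
  of stopping at the intermediate targets. `strokekin` quantifies this
  from the tangential-velocity profile, together with velocity-peak
  counts, spatial error against the target layout, and movement
  duration.
* **Slow tracking ("mirror game")** — a stylus follows a slowly
  oscillating 1-D stimulus built from half-sine velocity waves.  Humans
  cannot track very slow motion smoothly; they emit intermittent
  corrective adjustments visible as extra acceleration zero-crossings
  ("jitter").  `strokekin` detects jitter events, summarises their
  frequency distribution, and computes relative position / velocity /
  timing errors against the stimulus.

Because such recordings are rarely shareable, the package ships a
first-class synthetic-trajectory generator that produces ground-truthed
trials for both tasks (minimum-jerk stroke composition with controllable
overlap; stimulus programs plus followers with controllable jitter), so
every analysis stage can be validated by parameter recovery.

## The measures

**Coarticulation score.** After smoothing with least-squares cubic
regression splines (knots every 6 samples) and segmenting the movement
at 5% of the peak tangential velocity (requiring positive pen pressure
at onset), the speed profile's alternating peaks and troughs are
extracted.  With peak heights p₁..p₄ and trough heights t₁..t₃ in
temporal order,

    score = 100 · mean(t₁, t₃) / mean(p₁, p₂, p₃, p₄)

0 means four distinct point-to-point movements (full stops at the
via-points); 100 means no speed dip at all.  When strokes blend so far
that a peak–trough pair vanishes, the inflection point that replaced
them supplies one height used for *both* the missing peak and trough.

**Jitter.** The follower record is low-pass filtered (two-way 4th-order
Butterworth, 5 Hz cutoff), differentiated by finite differences and
resampled to 100 Hz.  Acceleration zero-crossings are kept if they are
not within 50 ms of a stimulus acceleration zero-crossing (those are
obligatory) and more than 200 ms from the previous retained event.  The
jitter frequency of a consecutive event pair is 1/(2·Δt) — the
frequency of the implied whole oscillation — and a trial or subject is
summarised by the peak of a Gaussian kernel density estimate over its
jitter frequencies.

**Tracking errors.** On the common 100 Hz grid, with follower x₁/v₁,
stimulus x₂/v₂ and centre position x_c:

    dX = (2/n) Σ |x₁−x₂| / |x₁+x₂−2x_c|
    dV = (2/n) Σ |v₁−v₂| / |v₁+v₂|
    dT = mean |Δt| between matched zero-velocity events

## Worked example

```python
import strokekin as sk
from strokekin.coarticulation import find_extrema, complete_profile, coarticulation_score

# a clean drawing trial with full stops, and one with 40% stroke overlap at B and D
for overlap in (0.0, 0.4):
    raw, truth = sk.generate_target_trial(sk.TargetTrialPlan(overlap=(overlap, 0.0, overlap)))
    series = sk.smooth_with_splines(raw)           # knots every 6 samples
    seg = sk.detect_bounds(series)                 # 5% of peak speed, pressure-gated
    profile = complete_profile(find_extrema(series, seg))
    res = coarticulation_score(profile)
    print(f"overlap={overlap:.1f}  score={res.score:5.1f}  n_peaks={res.n_peaks}")
```

prints

```
overlap=0.0  score=  0.1  n_peaks=4
overlap=0.4  score= 57.9  n_peaks=4
```

— the full-stop trial scores essentially zero (the scored troughs sit at
numerical zero), while blending 40% of each stroke into the next lifts
the troughs at B and D to ~58% of the mean peak height.

The command line mirrors the library:

```bash
strokekin simulate --manifest manifest.json --effects effects.json --out data/ --seed 1
strokekin analyze-target --input data/ --out results/
strokekin analyze-mirror --input data/ --out results/
```

Per-trial tables (`trial_results.csv`), per-subject per-phase summaries
(`summary.csv`) and a machine-readable run-log with the full
configuration are written to the output directory.

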