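# qpimass

Label-free, single-cell dry-mass profiling of T-cell-mediated cytotoxicity
from quantitative phase imaging (QPI) time-lapse stacks.

QPI measures the optical path difference (OPD) that light accumulates
through a cell, which is proportional to the cell's dry biomass. Live-cell
interferometry exploits this to watch cytotoxic T lymphocytes (CTLs) kill
cognate target cells without any labels: a killed target loses 20–60% of
its mass over 1–4 h after sustained CTL contact, while the attacking CTL's
mass-accumulation rate steps up ~4-fold and its mass ends up ~2.8× that of
unresponsive bystander T cells. `qpimass` implements the full computational
chain that turns raw wrapped phase images into those statements, plus a
phantom generator that renders fully ground-truthed synthetic stacks so
every stage is testable without a microscope.

## The measurement

Per detection, dry mass is

```
m = k · A_pixel · Σ OPD_i        k = 5.56 pg/µm³  (inverse specific
                                 refractive increment, Δρ/Δn)
```

with OPD in µm and `A_pixel` in µm². The pipeline stages, in order:

1. **phantom** — scripted scenes (growth, contact, ball-up, death,
   activation kinetics) rendered to wrapped phase + intensity stacks with
   per-pixel ground truth;
2. **unwrap** — minimum-discontinuity 2-D phase unwrapping (exact L1
   residue routing via min-cost flow; congruent to the input mod λ);
3. **wrapfix** — supervised repair of residual single-wavelength wrap
   errors: 16 per-pixel image statistics → Fisher linear discriminant →
   genetic refinement of score/watershed thresholds → ±λ region shifts →
   3×3 median filter;
4. **segment** — Gaussian low-pass, Otsu detection, per-cell mass
   integration over dilated supports, local-adaptive-threshold 2-D area;
5. **track** — squared-displacement-minimising assignment (Crocker–Grier
   style) with gap closure and merge bookkeeping for touching CTL–target
   pairs;
6. **massprof** — mass trajectories, normalisation, windowed
   mass-accumulation-rate fits (pre / first 100 min / post);
7. **events** — contact intervals, ball-up detection (t = 0), death
   confirmation, CTL activation metrics, and Welch-t population summaries.

## Worked example

Simulate ten CTL–target killing events and push them through the whole
pipeline:

```python
import numpy as np
from qpimass.pipeline import run_scenario

result = run_scenario("activation-default", seed=3)
for ev in result.events:
    r = ev.ctl_rates
    print(f"target {ev.target_track_id}: t0 = {ev.t0_min:5.1f} min, "
          f"loss = {100 * ev.mass_loss_fraction:4.1f}%, "
          f"CTL rates {r.r_pre:4.1f} -> {r.r_during:4.1f} -> {r.r_post:4.1f} pg/h "
          f"(x{r.during_pre_ratio:.2f})")
print("mean during/pre ratio:",
      round(float(np.mean([e.ctl_rates.during_pre_ratio for e in result.events])), 2))
```

prints (seed 3):

```
target 10001: t0 = 105.0 min, loss = 34.8%, CTL rates  6.1 -> 24.1 -> 12.3 pg/h (x3.97)
target 10002: t0 = 101.5 min, loss = 40.1%, CTL rates  6.3 -> 24.6 -> 12.2 pg/h (x3.93)
target 10005: t0 = 112.0 min, loss = 39.1%, CTL rates  5.2 -> 21.8 -> 11.1 pg/h (x4.16)
...
target 30006: t0 = 101.5 min, loss = 47.9%, CTL rates  6.1 -> 24.9 -> 12.1 pg/h (x4.10)
mean during/pre ratio: 4.04
```

Each line is one confirmed cytotoxic event: `t0` is the ball-up time (the
target rounds up and detaches, defining t = 0), `loss` the fraction of the
target's t0 mass lost within 4 h, and the rate triplet the CTL's
mass-accumulation rate before the event, during its first 100 min, and
after — the ~4× step-up is the label-free signature of CTL activation.

The same machinery runs from the shell:

```
qpimass simulate activation-default --seed 3 --out sim/
qpimass run      activation-default --seed 3 --out run/    # tracks.csv, events.json, summary.csv
qpimass evaluate activation-default --seed 3 --out metrics.json
```

`evaluate` scores the pipeline against the phantom's ground truth (mass
error distribution, track purity, event sensitivity/specificity).

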