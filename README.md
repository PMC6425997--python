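# uptakequant

Quantitative image analysis of large-particle internalization by human
B cells.

B cells can engulf whole micron-scale particles — antibody-coated bacteria,
3 μm beads — through their antigen receptor, not just soluble antigen. Two
measurements make this process quantifiable at scale, and this package
implements both as an open, tested pipeline:

1. **Internalization scoring** of imaging-flow-cytometry event images: per
   single-cell image, segment the cell and the particle, gate out events
   where the two are not in the same focal plane, and compute a
   radius-corrected centroid-distance score

       s = R / max(d, ε)

   with R the equivalent-circle cell radius, d the distance between the
   cell and particle centroids and ε a one-pixel floor. Membrane-bound
   particles give s < 1, engulfed particles give large s; events with
   s ≥ τ (τ = 2) are classified *internalized*, the rest *bound*. Cohorts
   are summarized as % interacting (particle-positive among in-focus cells)
   and % internalized (among particle-positive cells), and time courses as
   a trapezoidal area under the curve.

2. **Ratiometric FRET biosensor analysis** of RAC1 activation during
   engulfment: background correction, stack alignment, 3×3 smoothing,
   donor bleed-through correction (β = 0.62 by default, recalibratable from
   donor-only cells) and the acceptor/donor ratio F = (V − β·C)/C with
   background pixels as NaN, then the membrane-vs-cytosol activation ratio
   A(t) in the sector facing the particle contact site.

A **synthetic data module** generates ground-truthed event images and
biosensor stacks (geometry classes, defocus, photon-like noise, donor
leakage, stage drift), so every stage is validated against a known answer
without downloading anything. See `docs/methods.md` for models, parameters
and limitations.

## Worked example

Simulate a 200-event cohort (30% no particle, 30% bound, 30% internalized,
10% out of focal plane) and score it:

```text
$ uptakequant simulate events --n 200 --mixture 0.3,0.3,0.3,0.1 --seed 7 --out events
wrote 200 events to events
$ uptakequant score --in events --out scored
200 events: 68.0% interacting, 47.1% internalized
```

`scored/summary.csv` holds the gating chain behind those two numbers —
200 events total, 178 in focus (the 22 off-plane events were excluded by
the focus gate), 121 particle-positive (68.0% of 178), 57 of those with
s ≥ 2 (47.1% of 121):

```text
n_total,n_focused,n_particle_positive,n_internalized,pct_interacting,pct_internalized
200,178,121,57,68,47.1
```

`scored/features.csv` has the per-event geometry (R, d, s, focus metrics,
label) and `scored/score_histogram.png` the score distribution split at τ.

The same in Python, plus a biosensor movie with a 2×-activated contact
sector during frames 4–8:

```python
from uptakequant import synthetic as syn, events as ev, fret as fr

images, truths = syn.generate_cohort(200, (0.3, 0.3, 0.3, 0.1), seed=7)
features = ev.analyze_cohort(images)
print(ev.summarize_cohort(features["label"]))

truth = syn.make_fret_truth(frames=12, max_drift=3, seed=7)
stack, truth = syn.generate_fret_stack(truth, noise_sd=20.0, seed=7)
rmap, trace, shifts, masks = fr.run_fret_pipeline(stack, beta=0.62)
print(trace.to_dataframe().round(3))
```

The activation trace reads A ≈ 1.0 before and after engulfment and jumps to
≈ 1.95 while the contact sector is 2×-activated (the small deficit is the
documented smoothing bias at the band edge):

```text
 frame  time_min  membrane_mean  cytosol_mean  activation_ratio
     3       1.5          1.001         0.999             1.002
     4       2.0          1.976         1.012             1.953
     8       4.0          1.978         1.011             1.956
     9       4.5          1.001         1.000             1.001
```

Time-course quantification: `ev.auc_time_course((5, 10, 20, 30),
(10, 20, 40, 40))` → `775.0` %·min.

## Command-line interface

```text
uptakequant simulate events --n N --mixture p0,p1,p2,p3 --seed S --out DIR
uptakequant simulate fret   --frames T --beta 0.62 --seed S --out DIR
uptakequant score  --in DIR --out DIR [--threshold 2.0]
uptakequant fret   --in DIR --beta 0.62 --out DIR
uptakequant report --a A.csv --b B.csv [--column pct_internalized]
uptakequant run    --config config.json --out DIR [--seed S]
```

`run` executes simulate → score → summarize (→ fret) from a JSON config and
writes all tables, the resolved config, a log and a manifest of output
hashes; re-running the same config reproduces every table bit-identically.
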