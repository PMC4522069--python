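# t2mapping

Quantitative myocardial T2-mapping as a reusable, fully synthetic-testable
pipeline: simulation of multi-echo magnitude images for three cardiac
sequence designs, pixel-wise T2 reconstruction by maximum-likelihood
fitting under Rician noise, AHA-model segmentation of the left-ventricular
myocardium, and the paired statistics used to compare T2-mapping sequences
against a reference.

It is written for CMR (cardiovascular magnetic resonance) researchers who
want to study how sequence design and magnitude-noise statistics affect
estimated T2 relaxation times — without access to scanner data: every
stage runs on generated phantoms with known ground truth.

## The model

A T2-weighted series samples the monoexponential decay

    S(TE) = S0 · exp(−TE / T2)

at the echo (or T2-preparation) times of a sequence:

| sequence | sampling | times (ms) |
|----------|----------|-----------|
| MESE (reference) | 9 echoes | 12, 17.8, …, 58.4 (ΔTE 5.8) |
| GraSE | 9 echoes | 15, 22.7, …, 76.6 (ΔTE 7.7) |
| T2prep | 4 preparations | 0, 25, 50, 75 |

Magnitude MRI pixels are not Gaussian: with complex Gaussian noise of
scale σ per channel, the observed magnitude m is Rician,

    p(m | ν, σ) = (m/σ²) · exp(−(m²+ν²)/2σ²) · I₀(mν/σ²),   ν = S(TE),

which has a noise floor E[m] → σ√(π/2) as ν → 0. Ordinary least squares
on magnitudes therefore over-estimates T2 once late echoes approach the
floor. The per-pixel fit here maximises the Rician log-likelihood of
(S0, T2) — with σ fixed from a Rayleigh background estimate, or estimated
jointly — via bounded quasi-Newton iterations on (log S0, log T2),
multi-started from a log-linear initialiser and a coarse T2 scan.

Downstream, endo/epicardial contours define the myocardial annulus,
which is partitioned into equal angular AHA sectors (6 basal, 6 mid,
4 apical). Per segment the pipeline reports pixel count, mean T2, and
pixel SD; a segment is *inhomogeneous* when its pixel SD exceeds 20% of
its mean T2. Sequence comparisons use signed integer percent differences
against the reference, paired t-tests, and per-sequence mean ± SD with
95% t-intervals.

## Worked example

```python
import numpy as np
import t2mapping as t2

schedule = t2.build_schedule("GraSE")            # 15, 22.7, ..., 76.6 ms
vials = t2.default_vials()                       # 12 reference gel vials
sigma = min(v.s0 * np.exp(-schedule.times[0] / v.t2) for v in vials) / 50

stack, truth = t2.make_phantom(vials, schedule, sigma=sigma, seed=11)
maps = t2.fit_map(stack, truth.labels > 0, schedule, method="MLE", sigma=sigma)

sel = truth.labels == 2                          # vial 2: true T2 = 50.3 ms
print(round(np.nanmean(maps.t2_map[sel]), 2))    # -> 50.18
```

The fitted per-vial mean (50.18 ms at first-echo SNR 50) recovers the
generator truth within 0.3%; across all 12 vials (50–196 ms) the worst
per-vial error at this SNR is below 1%. `examples/` contains four short
narrative scripts — decay/noise model, phantom recovery, the cardiac
segmentation pipeline, and the paired sequence comparison — each printing
and explaining its numbers.

A thin CLI mirrors the library for shell use:

```bash
t2map simulate --kind cardiac --sequence MESE --sigma 0.5 --seed 1 --out run/
t2map fit --image run/stack.nii.gz --sidecar run/stack.json --sigma 0.5 --out run/maps
t2map segment --t2map run/maps/t2.nii.gz --contours run/contours.csv \
      --center 48 48 --out run/seg
t2map analyze --stats run/seg/segment_stats.csv --out run/homog
```

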