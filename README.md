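# synlab

Muscle-synergy analysis of locomotor EMG: non-negative matrix
factorization of lower-limb muscle activity into motor modules and
motor primitives, functional classification of the resulting
synergies, timing and duration geometrics, rescaled-range fractal
analysis, gait-parameter variability, and scalar + one-dimensional
statistical comparisons between locomotion conditions (walking vs.
running, overground vs. treadmill).

It is written for movement scientists who record multi-channel
surface EMG during gait and want a tested, scriptable implementation
of the modular-control analysis stack, including a synthetic-data
generator with known ground truth for validating every stage.

## The model

EMG envelopes from m = 13 lower-limb muscles, time-normalized to 200
points per gait cycle (100 stance + 100 swing), form a non-negative
matrix V (m × n). NMF with multiplicative updates factorizes

    V ≈ V_R = M P,

where M (m × r) holds the **motor modules** (time-invariant muscle
weightings) and P (r × n) the **motor primitives** (time-dependent
activation coefficients). Updates alternate

    P ← P ∘ (MᵀV) ⊘ (MᵀMP),   M ← M ∘ (VPᵀ) ⊘ (MPPᵀ),

stopping when the reconstruction R² changes by less than 0.01% over
20 iterations; each rank is fitted from 10 random restarts and the
factorization rank is chosen where the R²-vs-rank curve becomes
linear (iterative drop-and-refit with an MSE < 10⁻⁴ criterion).

Downstream, each primitive is characterized by its **center of
activity** (circular mean phase: CoA = atan2(Σ sinθ_t P_t, Σ cosθ_t P_t)),
its **full width at half maximum** (points above half max after
min subtraction), and its **Hurst exponent** H, the slope of
log(R/S) vs. log(N) over window halvings N = n, n/2, … ≥ 200, where
R/S is the range of the mean-centered cumulative sum divided by the
segment standard deviation. H < 0.5 indicates anti-persistent
(quasi-periodic) activation, H = 0.5 a memoryless series.

## Worked example

```python
import numpy as np
from synlab import synthetic, preprocess, nmf, metrics, fractal, gait

# a synthetic walking trial: 13 muscles, 2 kHz, 30 cycles,
# 4 ground-truth synergies + 5% envelope noise
bundle = synthetic.generate_trial(r=4, n_cycles=30, noise_sd=0.05, seed=11)

V = preprocess.preprocess_trial(bundle.raw, bundle.events)
curve, models = nmf.extract_synergies(V, n_restarts=10, seed=11)
rank = nmf.select_rank(curve)
model = models[rank].normalized()
print(f"selected rank {rank}, reconstruction R2 = {model.r2:.3f}")

for j in range(rank):
    coa = metrics.coa_to_points(metrics.trial_coa(model.P[j])[0])
    width = metrics.trial_fwhm(model.P[j])[0]
    h = fractal.hurst_rs(model.P[j]).h
    print(f"synergy {j+1}: CoA {coa:6.1f} pts, FWHM {width:5.1f} pts, H {h:.2f}")

s = gait.gait_summary(bundle.events)
print(f"stance CV {s.stance_cv:.1f}%, cadence CV {s.cadence_cv:.1f}%")
```

Output:

```
selected rank 4, reconstruction R2 = 0.970
synergy 1: CoA   73.3 pts, FWHM  27.2 pts, H 0.14
synergy 2: CoA  178.3 pts, FWHM  26.9 pts, H 0.25
synergy 3: CoA  131.4 pts, FWHM  21.9 pts, H 0.19
synergy 4: CoA   24.7 pts, FWHM  27.3 pts, H 0.13
stance CV 3.9%, cadence CV 2.2%
```

The four primitives center near points 25, 75, 130 and 178 — weight
acceptance, propulsion, early swing and late swing (NMF returns them
in no particular order) — matching the generator's ground-truth
peaks at 25/75/125/175; H < 0.5 reflects the anti-persistence of
quasi-periodic activation patterns. (CoA/FWHM are in normalized-cycle
points; stance spans points 0–99, swing 100–199.)

A thin CLI covers the core per-trial pipeline:

```bash
synlab generate --rank 4 --cycles 30 --seed 1 --out trial/
synlab extract --emg trial/emg.csv --events trial/cycle_times.csv --out syns.json
synlab report --model syns.json
synlab gait --events trial/cycle_times.csv
```

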