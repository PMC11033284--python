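# ricestore

Pesticide-residue dynamics in stored rice: simulation of residue decay under
temperature/humidity storage conditions, next-day residue forecasting with a
learning-to-rotate attention model, residue-based quality grading, and the
supporting degradation statistics.

## Who this is for

Food-safety and post-harvest researchers who want a tested, reproducible
implementation of a storage-quality workflow: given daily residue
concentrations of pesticides in stored grain under controlled temperature
(°C) and relative humidity (%), the package

1. **simulates** a realistic residue study when no measured data are at hand
   (five pesticides × eight condition series × 30 days = 1200 records),
2. **forecasts** the next day's residue per pesticide from a 7-day window
   plus the storage covariates,
3. **grades** lots by clustering the quality index `M = [d_current,
   d_predicted]` (measured residue paired with its forecast, mg/kg) with
   K-Means, choosing K ∈ {3,…,7} by mean silhouette, and
4. **summarizes kinetics**: first-order fits `ln C(t) = ln C₀ − k·t` with
   half-life `t½ = ln 2 / k`, Duncan's multiple-range test across storage
   conditions (compact letter display), and a quadratic response surface of
   half-life on coded factors A = (T−35)/5, B = (H−75)/5.

## The model at the core

The forecaster is a small encoder–decoder transformer whose attention
rotates each query/key channel pair (one complex plane per pair) by a
position-dependent angle

```
angle_p(m) = 2π · ω_p(m) · m + θ_p(m)
```

with per-plane frequency ω ∈ [0, 0.5] (cycles/step, Nyquist-bounded) and
phase θ ∈ (−π, π], both learned from the sequence content by a kernel-3
convolution. Scores use the rotated softmax kernel
`exp(⟨R(q)_m, R(k)_n⟩ / √d_h)`, which reduces exactly to standard scaled
dot-product attention at zero rotation. Attention is decoupled through a
learnable length-c global memory (compress the keys/values into c slots,
then let queries attend to the slots), so score evaluations grow as
`N·c + c·L` rather than `N·L`. Hidden states are trend-normalized: a
per-channel least-squares line over positions is removed, the residual
standardized, and the trend re-added with a learnable scale. Training
minimizes

```
L = L_pred + λ₁·L_ω + λ₂·L_θ ,
L_ω = mean squared step-to-step change of ω,   L_θ = mean |θ|
```

with Adam (cosine-decayed learning rate, gradient clipping), early stopping
on validation loss. Everything runs on numpy via a small reverse-mode
autodiff engine in `ricestore.autodiff`; no GPU or deep-learning framework
is required.

## Worked example

Forecasting one pesticide of the default study:

```python
import numpy as np
from ricestore import (StudyDesign, generate_study_dataset, QuatformerConfig,
                       make_windows, split_windows, train, evaluate_metrics)
from ricestore.pipeline import predict_windows

data = generate_study_dataset(StudyDesign(), seed=1)   # 1200 records
series = [s for s in data if s.pesticide == "imidacloprid"]
tr, va, te = split_windows(make_windows(series, input_len=7, horizon=1))
model, hist = train(QuatformerConfig(seed=7), tr, va)
pred = predict_windows(model, te)
rep = evaluate_metrics(np.stack([w.target for w in te]), pred)
print(f"test MSE {rep.mse:.2e} mg²/kg², SMAPE {rep.smape_pct:.2f}%")
```

prints (with exactly these seeds)

```
test MSE 1.12e-03 mg²/kg², SMAPE 7.12%
```

— the held-out next-day error is small against the 0.26–0.58 mg/kg residues
of the test horizon (the study's default 5 % observation noise included).
Grading a batch of lots with known residue tiers:

```python
from ricestore import kmeans, select_k, grade_clusters
from ricestore.synthetic import generate_tiered_m_samples

pts, _ = generate_tiered_m_samples([0.6, 1.5, 2.6], 0.12, 40, seed=1)
best_k, sil = select_k(pts, range(3, 8), seed=1)
gm = grade_clusters(kmeans(pts, best_k, seed=1), pts)
print(best_k, dict(sorted(sil.items())), gm.intervals(), sep="\n")
```

```
3
{3: 0.845, 4: 0.720, 5: 0.603, 6: 0.495, 7: 0.482}
[('High', '(0, 1.04202)'), ('Medium', '[1.04202, 1.99253]'), ('Low', '(1.99253, +inf)')]
```

— the silhouette criterion recovers the three planted tiers, and lots whose
current residue sits below 1.04 mg/kg (and is forecast to fall, per the
paired coordinate) grade High.

The end-to-end pipeline — simulate → train → forecast → grade → statistics,
with all artifacts and a run manifest on disk — is one call
(`ricestore.io.run_pipeline`) or one command (`ricestore run --seed 1 --out
results/run`). The numbered scripts under `analysis/` run the same stages as
a narrated sequence and write their tables under `results/`.

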