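# Methods

## Scope and data model

The package models the fate of pesticide residues in stored rice as a set of
per-pesticide, per-condition daily concentration series (mg/kg) and builds
four stages on top of them: a synthetic study generator, a next-day residue
forecaster, a residue-based quality grader, and degradation statistics. The
canonical record is `(pesticide, temperature_C, rh_pct, day, conc_mgkg)`;
all tabular artifacts are comma-separated UTF-8 text.

## Synthetic study generator

No public residue dataset accompanies this problem setting, so the generator
is first-class, tested code that defines the study conditions everything
else is evaluated under.

**Design.** Five pesticides (imidacloprid, carbaryl, fenitrothion,
chlorpyrifos-methyl, deltamethrin), each observed daily for 30 days under
two one-factor sweeps: temperature 25/30/35/40 °C at 65 % RH, and humidity
65/70/75/80 % at 25 °C. The shared 25 °C/65 % condition belongs to both
sweeps and is generated once per arm, so the default design counts 8
condition series per pesticide and 5 × 8 × 30 = 1200 records. A
`deduplicate` flag collapses the shared arm for users who prefer 7 unique
conditions.

**Decay law.** Concentrations follow a two-compartment (bi-exponential)
decay

    C(t) = C0 · [ f · exp(−k_f t) + (1 − f) · exp(−k_slow t) ],

chosen because observed dissipation curves drop fast early and flatten
later; a single-exponential is the `f = 1` special case. Defaults put the
fast phase mostly inside the first week (peak fast rates 0.40–0.55/day) for
four pesticides and give chlorpyrifos-methyl a much smaller peak fast rate
(0.18/day) so its curve flattens around day 15 instead of day 7.

**Condition response.** The fast rate responds to temperature and humidity
through a Gaussian in each factor,

    k_f = k_base · exp(−(T−T_opt)²/2σ_T²) · exp(−(H−H_opt)²/2σ_H²),

so degradation accelerates with rising temperature (or humidity) up to a
critical point and slows beyond it — the rate is unimodal with its maximum
at `(T_opt, H_opt)`. Defaults (`T_opt` 36–39 °C, `H_opt` 76–79 %) keep the
rate mostly increasing over the study range while leaving the peak close
enough that half-life surfaces are non-monotone. `σ_T` ≈ 7–9 °C and `σ_H` ≈
13–15 % set how sharply the response falls off.

**Noise.** Observations are the mean curve times lognormal(0, σ) noise
(default relative σ = 0.05), clipped at zero; concentrations are positive so
multiplicative noise is the natural choice. One root seed drives
everything; per-series sub-seeds are derived by hashing (pesticide,
condition), so any subset of the study reproduces bit-exactly.

**What the generator does not emulate.** Mechanistic chemistry
(Arrhenius/hydrolysis kinetics), analytical measurement error structure
(LOQ censoring, batch effects), microbial or toxin co-dynamics, and
between-lot heterogeneity. Tests passing on this generator demonstrate the
pipeline's correctness and calibration under controlled decay + lognormal
noise, not performance on laboratory data.

**Clustering fixtures.** `generate_tiered_m_samples` plants well-separated
residue tiers: `d_current` Gaussian around each tier center,
`d_predicted = d_current · U(0.85, 1.0)` (a forecast of a decaying residue
should not exceed the current value).

## Forecaster

A small encoder–decoder transformer over windows of `input_len = 7` days
with three features: concentration plus the two (constant per series)
covariates temperature and humidity, z-scored with training-set statistics
only.

**Learning-to-rotate attention.** Each head's width `d_h` is split into
`P = d_h/2` channel pairs, each treated as one complex plane. Query/key
vectors are rotated plane-wise by `angle_p(m) = 2π ω_p(m) m + θ_p(m)`;
frequencies and phases are produced from the sequence content by a kernel-3
convolution with replicate padding, squashed by `0.5·sigmoid` (Nyquist band
[0, 0.5] for unit-step sampling) and `π·tanh` respectively. Scores are
`exp(⟨R(q)_m, R(k)_n⟩/√d_h)`; the `1/√d_h` scaling is kept for numerical
stability and the zero-rotation case is verified against an independently
coded softmax attention. The phase enters the angle additively even though
it could be folded into the vector, because the phase penalty below would
otherwise regularize a dead parameter. Queries and keys are rotated in the
same plane with independent learned parameters; a genuinely distinct
two-plane (quaternion i/j) construction is not attempted because no
channel-to-plane mapping is specified anywhere, and the shared-plane real
part reproduces the relative-rotation semantics.

**Decoupled attention with global memory.** Each attention block owns a
learnable memory of `c = 8` slots. Stage 1 compresses the key-value
sequence into the slots (`M′ = Attn(memory, kv, kv)`); stage 2 lets the
queries attend to `M′`. Score evaluations therefore number `N·c + c·L`,
linear in both lengths at fixed `c`; an instrumented counter
(`quatformer.score_counter`) exposes the exact count and the tests assert
the formula rather than wall-clock time. The rotation parameters for the
memory slots and for `M′` come from their own content; the `M′` learner is
shared across heads.

**Trend normalization.** Instead of layer statistics, each channel is
normalized about its slowly changing temporal trend: fit a least-squares
line over positions, standardize the residual (ε = 1e−5), re-add the trend
scaled by a learnable ρ, with per-channel gain γ and shift β:

    out = γ · (h − Tr)/(sd(h − Tr) + ε) + β + ρ·Tr.

A purely linear input passes through unchanged (γ = ρ = 1, β = 0), and the
output's residual about ρ·Tr has zero fitted slope.

**Decoder input.** The decoder sees the last `label_len = 3` observed steps
plus `horizon` placeholder steps whose concentration channel is zero but
whose covariates are the (known, constant) storage conditions — the
standard informer-style arrangement; nothing in the problem fixes this, so
it is a design choice. A linear head on the horizon positions emits
standardized predictions, de-standardized back to mg/kg.

**Loss and regularization.**

    L = L_pred + λ₁·L_ω + λ₂·L_θ,
    L_ω = (1/P(N−1)) Σ_p Σ_n (ω_p^(n+1) − ω_p^(n))²,
    L_θ = (1/PN) Σ_p Σ_n |θ_p^(n)|,

averaged over every rotation-parameter instance (query and key side of
every attention in every layer). λ₁ = λ₂ = 0.01 by default — small enough
not to distort the fit, large enough to keep the learned frequencies smooth
and the phases sparse.

**Optimization.** Adam, base learning rate 1e−2 with cosine decay to 1 % of
the base over the epoch budget, mini-batches of 16, gradient clipping at
global norm 1, early stopping on validation prediction loss with patience
10, best-validation weights restored. The comparatively aggressive base
rate plus decay is deliberate: the one-step-ahead task on slowly decaying
series demands prediction errors well below the one-day decay increment
within a ~100-epoch budget, and a flat 1e−3 rate plateaus an order of
magnitude short of that. All initialization flows from the config seed;
identical seeds give identical loss histories on one machine.

**Model size.** Defaults: d_model 32, 4 heads, 1 encoder + 1 decoder layer,
feed-forward width 64, memory 8 slots — a few thousand parameters, trained
per pesticide (the study never pools pesticides, and their decay regimes
differ).

The model runs on a purpose-built reverse-mode autodiff engine
(`ricestore.autodiff`) over float64 numpy arrays: a `Tensor` graph with
broadcasting-aware gradients, verified against central finite differences
in the test suite.

## Splitting and evaluation

Windows are stride-1 and per-series; splits are chronological within each
series (70/10/20 by default) so no training anchor postdates a test anchor —
with 23 windows per 30-day series this gives 16/2/5. Metrics: MSE, RMSE,
MAE, and percent-scale MAPE and SMAPE (SMAPE denominator `(|ŷ|+|y|)/2`);
exact 0/0 terms contribute zero, and a zero truth with nonzero prediction
makes MAPE infinite with a warning rather than an exception. The
persistence baseline repeats the last observed concentration — on a
noiseless decaying series its error is exactly the one-day decay increment,
which makes it a demanding reference on slowly changing data.

## Quality grading

The grading feature is the pair `M = [d_current, d_predicted]` (mg/kg),
kept unscaled: both coordinates share units and a scale would change
cluster geometry silently. Clustering is per pesticide.

K-Means is Lloyd's algorithm exactly — assign to the nearest centroid
(Euclidean; ties to the lowest centroid index), recompute centroids as
coordinate means, stop at a fixed point or 300 iterations — with k-means++
seeding, 10 restarts keeping the best inertia, and empty clusters re-seeded
at the farthest point. On small instances this provably attains the
enumerated global optimum (tested exhaustively for n ≤ 8, K ∈ {2,3}).

K is selected in {3,…,7} by the mean silhouette
`S = (1/N) Σ (b−a)/max(a,b)` with singleton clusters and 0/0 cases
contributing zero; ties break toward smaller K (fewer grades are easier to
regulate with).

Grades order clusters by ascending center `d_current` — lower residue is
better quality — and the breakpoint between adjacent grades is the midpoint
between the better cluster's maximum and the worse cluster's minimum on the
`d_current` axis (the interval table is one-dimensional while M is
two-dimensional; the midpoint rule is the natural projection). Intervals
follow the bracket pattern `(0, b₁)` / `[b₁, b₂]` / … / `(b_last, ∞)`, so a
value landing exactly on a cut belongs to the closed middle interval.
Non-increasing breakpoints (possible only for pathological, interleaved
clusterings) raise an error naming the offending pair.

## Degradation statistics

**Kinetics.** Ordinary least squares on `ln C(t)` over strictly positive
observations gives `k` and `t½ = ln 2/k`; `r²` of the log-linear fit is
reported as a lack-of-fit diagnostic, since the generator's truth is
bi-exponential and the single-exponential summary is the standard
residue-dissipation convention. A non-positive slope reports an infinite
half-life with a warning. With 5 % multiplicative noise and 31 daily
points, the median relative error of `k` is well under 10 %.

**Half-life response surfaces** are fitted on the 3×3 factorial over coded
levels A, B ∈ {−1, 0, +1} (30/35/40 °C, 70/75/80 % RH) as
`y = β₀ + β₁A + β₂B + β₃AB + β₄A² + β₅B²`, with an evaluator over the coded
square and the stationary point of the quadratic. Surface half-lives are
fitted over the first week of storage (the active dissipation phase): over
the full 30-day horizon the log-linear slope is dominated by the slow tail,
which inverts the condition response and buries the dip-then-rise shape the
surface is meant to exhibit. Rank-deficient designs are rejected naming the
unidentifiable terms.

**Duncan's multiple-range test** follows the classical recipe: one-way
ANOVA `MS_error` and df, means ranked, critical range for a stretch of `p`
ranked means `R_p = q(1−α_p, p, df)·√(MS_error/n)` with protection level
`α_p = 1 − (1−α)^(p−1)` (studentized-range quantiles from scipy), protected
sequential testing (a stretch inside a retained non-significant stretch is
never declared), harmonic-mean `n` for unequal groups, and an
insert-and-absorb compact letter display ("a" on the largest mean).
Degenerate inputs are fixed by convention: zero error variance with unequal
means → all distinct; all observations identical → one shared letter. The
test is applied to monotone-decreasing residue series exactly as the
field's tables do, normality notwithstanding; the null calibration check in
the test suite (3 equal-mean normal groups, n = 30, α = 0.05, 500
replicates) verifies the familywise any-difference rate sits near the
nominal level.

## Problem sizes and runtime choices

The packaged defaults are the study conditions: 1200 records, 23 windows
per series, per-pesticide models of a few thousand parameters, ≤ 100
epochs. The heaviest check in the suite — five seeds × five pesticides of
forecaster training against the persistence baseline — uses 70 of the 100
budgeted epochs per model; the end-to-end pipeline and the acceptance
script use the full default budget. Simulation-based checks (kinetics
noise recovery, Duncan calibration, tier-recovery) use 20–500 seeded
replicates as stated in their tests.

## Known limitations

- The forecaster is evaluated on the synthetic study only; no claim is made
  about laboratory residue data, measurement censoring, or regime changes.
- One model per pesticide: no cross-pesticide transfer, no global model.
- The grade intervals project a 2-D clustering onto the current-residue
  axis; two samples with equal `d_current` but very different forecasts can
  straddle a grade boundary only through the clustering, not the intervals.
- Duncan's test assumes exchangeable normal errors that the decaying series
  violate by construction; it is provided because it is the field's
  convention, with the caveat on record here.
- The autodiff engine implements exactly the operations the model needs; it
  is not a general-purpose framework (no second derivatives, no in-place
  aliasing guarantees).
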