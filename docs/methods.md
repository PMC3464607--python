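# Methods

## The signal model

A cluster of identical template copies emits, at chemistry cycle
t = 1..L, a 4-vector of channel intensities. The model has five layers:

1. **Phasing / pre-phasing.** Each strand independently fails to extend
   with probability p or extends by two bases with probability q. The
   strand-length state 0..L therefore follows a Markov chain with an
   (L+1)×(L+1) transition matrix P (p on the diagonal, 1−p−q one above,
   q two above). Transitions that would overshoot length L deposit their
   mass on state L, which is absorbing — the chain stays stochastic and
   the L×L truncation of the profile matrix
   H[i,j] = [P^j]<sub>1,i+1</sub> is well defined. Column t of H
   describes how much each template position contributes to the cycle-t
   signal; because p and q are small it is dominated by the l+r+1
   entries around position t, and the caller uses only that window
   (default l = r = 1; the 64-state window chain).

2. **Density decay.** The per-cluster amplitude follows
   λ_t = (1−d_t) λ_{t−1} (1+ε_t), ε_t ~ N(0, σ_t²), with λ_1 = 1.
   d_t and σ_t are treated as per-cycle, per-cluster hidden draws from
   uniform distributions; only the means and variances (d_mean, d_var,
   σ_mean, σ_var) are parameters. The uniform with given mean m and
   variance v is the unique one on [m−√(3v), m+√(3v)]; endpoints are
   clipped to the admissible range with a warning, since clipping
   perturbs the moments. λ is clipped at 0 in the samplers (the decay
   recursion itself is not truncated; the simulator warns if a negative
   λ is drawn, which at realistic σ essentially never happens).

3. **Crosstalk and noise.** y_t = K_t x_t + ‖x_t‖·η, η ~ N(0, Σ_t):
   noise scale follows the signal, so the covariance is ‖x_t‖²Σ_t.

4. **Residual carry-over.** A fraction α_t(1−d_t) of the previous
   cycle's *measured* intensity leaks into cycle t. Removing it
   (y″_t = y_t − α_t(1−d_t)y_{t−1}, y_0 = 0) restores the conditional
   independence structure of an HMM. The correction uses the central
   decay value d_mean; the simulator applies the *realized* d_t, so the
   correction is exact only when d_var = 0 — the residual mismatch at
   d_var > 0 is part of the model error the benchmarks measure.

5. **Template prior.** Bases are i.i.d. uniform over {A, C, G, T}
   (convention: channel 1 = A, 2 = C, 3 = G, 4 = T; ties in argmax
   calls break lexicographically A < C < G < T). Cycle indices are
   1-based at every interface.

The simulator draws from the **exact** model (full profile column h_t,
no windowing) while the callers use the windowed approximation —
deliberately, so the window truncation error is included in what
end-to-end tests measure.

## Inference

**Plain SISR filter.** Particles carry (S_t^w, λ_t) plus fresh per-cycle
draws of (d_t, σ_t); the proposal is the model transition (window shifts
left, incoming base uniform, λ from the decay law), weights are
multiplied by the observation density and kept in log space with
max-shift normalization. The filtered posterior of the centre column is
read off *before* resampling; multinomial resampling triggers when
K_eff ≤ N_p/2. When ‖x^w‖² < 1e−8 the covariance scale is clamped there
so the density stays proper near λ = 0.

**Rao-Blackwellized filter.** The discrete window states are summed out
exactly: each particle carries a 4^(l+r+1)-vector posterior over window
states, updated by a shift-structured prediction and a log-space
likelihood multiplication; the weight update is the marginal likelihood
Σ_s p(y″_t|s, λ) p(s|past). The λ-transition density cancels in the
discrete normalization. Resampling duplicates the discrete posterior by
value. The per-base posterior is the weight-averaged centre-column
marginal. The batched implementation expands the Gaussian quadratic
form analytically so no (reads × particles × states × 4) array is
materialized.

**λ₁ initialization.** λ₁ is drawn from N(1, v₁) where v₁ is the sample
variance of a crude per-cycle density proxy — the total
crosstalk-inverted intensity Σ_b[K⁻¹y_t]_b over the first 10 cycles —
floored at 1e−4. When the parameter set makes λ deterministic
(σ ≡ 0 and d_var ≡ 0 in every window) the model itself pins λ₁ = 1 and
the point-mass initialization is used instead; with a near-singular Σ a
continuous λ₁ spread would otherwise collapse the ensemble onto a
single particle at cycle 1 and freeze the not-yet-observed window
column. `init_lambda_sd` overrides either behaviour.

**Exact references.** Conditional on a fixed λ path, the forward
recursion over the 4^(l+r+1) window states gives the exact filtered
posteriors; it is the oracle for both filters in the σ = 0 regime. An
independent brute-force route enumerates all 4^L templates and scores
them with scipy's multivariate normal; the two agree to 1e−10 on 5-cycle
problems, and the RB filter reproduces the recursion to machine
precision for any particle count.

**Known limitation — particle poverty of the plain filter.** The
observation at cycle t carries only a sliver of information (the
pre-phasing mass H[t+1,t] ≈ q·t) about position t+1, yet resampling at
cycle t commits the ensemble to that sliver posterior before the
decisive observation arrives. When the one-step-ahead posterior is
occasionally misleading, correct-hypothesis particle counts can hit
zero, producing short runs of confident wrong calls. The loss shrinks
roughly linearly in 1/N_p (≈5·10⁻³ at N_p = 200, ≈5·10⁻⁴ at N_p = 800
under the default preset) and the Rao-Blackwellized variant is immune,
which is precisely its practical advantage.

## Parameter estimation

Phasing p, q are inputs (lane-level quantities supplied by the
platform); a coarse grid-search helper over the particle-filter
log-evidence is provided as a convenience, not as part of the standard
procedure.

**Early-cycle initialization.** For the first ~10 cycles phasing is
negligible and x_t ≈ λ_t s_t. A fixed-point loop (4 passes) alternates:
residual-correct with the current coefficient; identify bases as the
argmax of K⁻¹y″; proxy λ̂_t as the identified channel; re-fit K by
column-separable least squares; re-fit the residual coefficient
α(1−d) by lag-1 regression of the fit residuals on y_{t−1}. Σ is the
covariance of the standardized residuals. d_mean comes from the decay of
the cross-read mean of λ̂ (measurement noise averages out); the combined
spread σ² + var(d) comes from the *growth rate* of the cross-read
squared coefficient of variation of λ̂ (λ₁ = 1 exactly, so the intercept
is the measurement floor and the slope isolates the model variance).
One growth rate cannot separate its two sources, so it is split evenly,
with d_var capped so the uniform interval stays inside [0,1]; both
assignments are exact in the degenerate cases (constant d, σ = 0).
σ_var is initialized at 0.

**Particle-filter EM.** Windows of w = 5 cycles are processed left to
right; each window runs 30 EM iterations with 600 trajectories per read
from an SISR filter warm-started from the previous window's final,
equally weighted ensemble (a closing resampling pass makes trajectories
equally weighted, with ancestral reindexing inside the window). The
M-step maximizes the Monte Carlo average of the complete-data
log-likelihood in closed form — these are the stationarity conditions of
the Gaussian observation model:

* α: scalar weighted least squares of (y_t − K x^w_t) on (1−d_t)y_{t−1},
  using each trajectory's realized d_t, with the current K, Σ;
* K: weighted multivariate least squares of y″ on x^w, weights 1/‖x^w‖²;
* Σ: weighted covariance of the residuals (y″ − Kx^w), same weights;

iterated once per M-step. d and σ moments are *not* re-estimated by EM;
they come from the initialization and are shared by all windows. The
surrogate objective is monitored; decreases beyond a Monte Carlo jitter
band (0.15 per-sample units at the standard 200-read × 5-cycle size,
scaled by the usual square-root law) are logged as warnings. The
E-step trajectories are filtered rather than smoothed draws — the
smoothing alternative would be statistically tighter but is not what
the windowed warm-start scheme produces; at w = 5 the difference is
absorbed by the EM iterations. Training reads are subsampled once
(seeded, without replacement) and reused for every window.

Identifiability note: per-window K estimates from 5 cycles × 200 reads
are noise-limited (the 0.1 bleed entries carry ≈0.02 sampling noise per
window). When the truth is window-constant, the window-averaged K (and
Σ, α) is the meaningful recovery target; per-window values are reported
as estimated.

## Quality scores

Predicted per-base error probability is 1 − p(ŝ_t | y″_{1:t});
phred = round(−10 log₁₀ ·), floored at 0 and capped at Q_MAX = 60
(posterior mass 1 would give an infinite score, and 1e−6 is beyond the
resolution of an N_p ≤ 2000 particle posterior). Error rates are plain
mismatch fractions against simulator truth — no reference alignment or
read filtering is involved, so every base is counted. The
discrimination score D(ε) counts bases that are both correct and have
predicted error < ε, over all called bases; it is non-decreasing in ε by
construction and asserted on every curve. Calibration is assessed by
binning bases on predicted error probability over half-decade log bins
spanning [1e−3, 1]; bins below the filter's Monte Carlo resolution
(≈1/N_p — there the posterior is exactly 1 and the prediction is not
estimable) are reported but not held to the factor-of-2 comparison.

## Synthetic study conditions

The default preset aims at the operating regime of a real Genome
Analyzer tile: p = 1e−7 and q = 3e−3 (the magnitudes estimated on real
data), d_mean = 0.01 with uniform half-width 0.005, σ_mean = 0.02 with
half-width 0.01, α = 0.2, K = identity with 0.1-level bleed inside the
A/C and G/T dye pairs, and Σ = 0.25²·I. The noise scale is the one
deliberate design choice: because the model's noise follows ‖x‖², the
signal-to-noise ratio is constant over cycles, and a small Σ would make
the channel essentially error-free — naive argmax calling would be
perfect and nothing could beat it. Σ = 0.25²·I places the error rates
of all callers in the ~10⁻² regime observed on real instrument data,
where the comparisons between callers are meaningful. The "noiseless"
preset switches every stochastic channel off (Σ = 1e−12·I keeps the
observation density proper) and is the end-to-end identity check:
both callers must recover every base.

What the simulator does **not** emulate: correlated template bases
(real genomes are not i.i.d.), per-cluster crosstalk variation, spatial
tile effects, absolute noise floors independent of the signal, image
registration artifacts, and cluster-density-dependent effects. Passing
the synthetic benchmarks therefore shows the inference machinery is
correct and calibrated *under the model*, not that the model captures
every property of real instrument data.

## Problem sizes and numerical choices

The test suite and the acceptance script use fixed seeds throughout and
these sizes, chosen to exercise each claim at meaningful precision on a
single CPU: 200×76 reads for the noiseless identity, 1000×76 (tests) /
600×76 (script) for the plain-vs-RB comparison and calibration, 20×20
with N_p = 20,000 for plain-filter convergence, 5-cycle problems for the
enumeration cross-check, 200 training + 200 held-out reads at L = 40 for
estimation, and 3-point noise grids × 10 seeds × 40 reads for the
monotone-degradation scan. Other constants: covariance floor 1e−8 on
‖x^w‖²; λ₁ variance floor 1e−4; Σ estimates ridged by 1e−10·I (1e−8·I at
initialization); weights normalized by log-sum-exp with max shift; the
RB discrete update performed in log space so zero-support states stay
zero and a particle whose predicted support vanishes is marked dead
(weight −∞) rather than propagating NaNs.
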