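# Methods

This note records the statistical models implemented in `zfhunt`, the
choices made where the design was genuinely open, and what the synthetic
generators do and do not emulate.

## Models

### Hunt-rate / duration / attempt counts

Between-larva variability in hunting drive makes a single Poisson rate
untenable, so per-larva counts follow a Gamma–Poisson mixture: larva *i*
hunts at rate `λ_i ~ Gamma(α, β)` and produces `h_i ~ Poisson(λ_i)` events
per 10-minute recording. Marginally `h ~ NB(r, q)` with `r = α`,
`q = β/(1+β)`; the group mean rate is `λ = r(1−q)/q`. Priors are
`q ~ Uniform(0,1)` and `r ~ Gamma(1,1)`. Total hunt *duration* is treated
identically, with the count being the number of video frames spent in hunt
mode; larvae with zero hunt events are excluded there, because a detected
event lasts ≥ 100 frames and zeros make the frame-count distribution
discontinuous. The posterior NB mean is converted frames → seconds by
dividing by the frame rate (410 fps). The capture model adds
`Ns ~ Binomial(h, p_s)` with `p_s ~ Beta(1,1)`; because the attempts `h`
are observed, `p_s` is conditionally conjugate and sampled exactly from
`Beta(1+ΣNs, 1+Σ(h−Ns))`.

Sampling: adaptive random-walk Metropolis on `(log r, log λ)` — in that
parametrization the posterior is close to elliptical, and split-R̂ stays
below 1.02 in routine use. A 2-D grid-quadrature oracle over `(r, q)`
validates the posterior means to 2%.

### First-turn regression

For pooled (azimuth θ, first turn φ) pairs of one group,
`φ ~ N(β0 + β1 θ, σ²)` with `σ² ~ InvGamma(5, 2)`,
`β0 ~ N(0, precision 2)`, `β1 ~ N(0, precision t1)`, `t1 ~ Gamma(1,1)`
(normal distributions parametrized by precision throughout). The model is
fully conditionally conjugate and is sampled by Gibbs. Angles are kept in
degrees and signed; mirror symmetry of the detector pipeline makes the
sign convention immaterial for the slope. Pooling across larvae is
deliberate — it reproduces the per-event analysis, whose bias toward
active individuals the hierarchical group model removes.

### Fast/slow capture mixture

(speed, distance) points of successful captures follow a two-component
bivariate normal mixture with per-point label prior 0.5. Priors: slow
speed mean centred at 5 mm/s, fast at 35 mm/s; `σ_s^slow ~ U(0,2)`,
`σ_s^fast ~ U(0,10)`, `σ_d ~ U(0,1)`, `ρ ~ U(−1,1)`; distance means
`N(0.5, precision 10)` for both clusters. The printed precision on the
speed means ("10¹²") would pin them and contradict the data-informed
cluster centres reported alongside, so we use a weakly-informative
precision of 10⁻² (sd 10 mm/s), exposed as `speed_mean_precision`.
Identifiability is by ordering — the fast cluster keeps the larger mean
speed in every draw — rather than initialization luck. Sampling is Gibbs:
exact label draws, conjugate mean updates (rejected if they would violate
the ordering), adaptive Metropolis on `(σ_s, σ_d, ρ)` per cluster. A point
is labelled fast when its expected membership across draws exceeds 0.7;
the fast fraction is reported with a Normal(·, 0.03) smoothing density.
An exhaustive 2⁶ label-assignment enumeration validates the per-point
membership under fixed parameters.

### Hierarchical group behavior

Events `x_ij = (speed, distance, turn-ratio)` are MVN around a per-larva
mean `m_i`, and larva means are MVN around the group mean `μ_g`:

    x_ij ~ MVN(m_i, Σ_w),   m_i ~ MVN(μ_g, Σ_b)

with `μ_g ~ MVN(column medians, diag((10·sd)²))` and each covariance
decomposed into scales (half-normal, prior scale 5× the empirical column
sd) and a correlation matrix (uniform over valid correlation matrices).
The within-larva covariance is shared across larvae (the per-larva
alternative is noted but not implemented). The sampler is a collapsed
Gibbs: larva means are integrated out analytically
(`x̄_i ~ MVN(μ_g, Σ_b + Σ_w/n_i)` plus a pooled-scatter term), `μ_g` is
then conjugate, and the twelve covariance parameters move by componentwise
adaptive Metropolis on the collapsed likelihood. Collapsing removes the
funnel between `Σ_b` and the larva means that made the uncollapsed Gibbs
mix poorly (R̂ up to 1.5 on the distance scale); all parameters now sit
below R̂ ≈ 1.02. Larva means are re-drawn conjugately for reporting.
A `fixed_cov` mode pins both covariances, making the `μ_g` posterior
exactly conjugate — the test suite uses it as a closed-form oracle.

### Behavior space and efficiency prediction

Each larva with ≥ 5 capture attempts contributes a six-vector
(efficiency `Ns/h`, attempts, mean speed, mean distance, mean turn-ratio,
mean time-to-prey); kinematic entries are model-estimated per-larva means
by default, empirical means as a fallback. Standardization is
`(x − μ_x)/σ_x` with the turn-ratio centred at 1 (perfect aim) instead of
its mean. The published vector definition lists five elements in one place
and six (adding time-to-prey) in another; the six-dimensional version is
the default with a `six_dimensional=False` switch. PCA is the
eigendecomposition of the covariance of the standardized matrix with a
deterministic sign convention. PCR regresses efficiency (on its original
scale) on the leading PC scores of the five predictor covariates;
efficiency is excluded from the predictor matrix by default so the
prediction is leakage-free (the embedding-with-efficiency variant used for
visualization is available separately via `exclude_response=False`).
Prediction error is a 10-fold seeded cross-validated RMSEP; its
"coefficient of variation" divides by the response mean (response sd
selectable — the source does not define it).

### Posterior comparisons

`P[a > b]` is the fraction of paired draws with `a_i > b_i`; ties count
one half; unequal draw vectors are cycled to a common length. MCMC
contract: ≥ 3 chains, ≥ 2000 retained draws, split-R̂ < 1.05 on reported
parameters (checked via `arviz`; violations warn rather than fail).

## Event detection

Detection constants are the published ones: vergence ≥ 45°, each eye ≥ 19°
inward (inward = toward the midline: left ≥ +19°, right ≤ −19° under the
clockwise-positive convention), minimum 100 frames, concatenation of runs
< 300 frames apart. Concatenation is applied **before** the
minimum-duration test, so two short runs with a small gap can form one
valid event; the source states both rules without fixing the order.
Filtering is zero-phase (forward–backward) to avoid lag bias at event
boundaries, and detection runs on the filtered vergence. Turn-ratio is
undefined for |θ| < 3° to keep γ bounded. The mouth tip is approximated as
the head reference advanced 0.5 mm along the heading; "the head passes the
prey" is operationalized as the closest-approach frame.

## Synthetic world

The generators' defaults are the printed group summaries: evoked/spontaneous
hunt-rate means 13.3/3.6 (LF), 11.9/3.8 (NF), 12.1/3.5 (DF); evoked
durations 35.5/47/42.5 s at 410 fps; attempt means 10.9/9.2/8.9 with
success probabilities 0.32/0.21/0.18; turn slopes 0.73/0.87/0.92;
fast-capture fractions 0.41/0.28/0.21; group mean vectors (28.2 mm/s,
0.35 mm, 0.85), (17.5, 0.23, 0.94), (23.3, 0.24, 0.92); successful-event
counts 92/69/45. Values the source does not state were fixed once:

- NB size r = 3 for every count distribution (overdispersion of the same
  order as the published CDF spread);
- turn noise sd 10° (homoscedastic, in degrees), giving sub-0.05 slope
  posterior sds at n ≈ 90;
- prey azimuths uniform over ±[35°, 50°] (the detection band reported as
  most likely), mirror-symmetric;
- hierarchy between-larva sds (4 mm/s, 0.08 mm, 0.08) and within-larva sds
  (6 mm/s, 0.12 mm, 0.12), with 1–6 events per larva;
- trace plateau vergence 60° (30° per eye), eye jitter sd 2° — comfortably
  inside the 45°/19° rule; head drift ~0.4 mm/s, well under the 4 mm/s
  bout threshold;
- per-larva mean time-to-prey lognormal around 60 ms.

Traces with embedded kinematics place a stationary prey at a configured
azimuth, execute a first turn of magnitude `turn_ratio × azimuth` confined
to the super-threshold core of a 12 mm/s turn bout, and lunge through the
prey with a raised-cosine speed pulse peaking at the configured capture
speed, launched from exactly the configured mouth-to-prey distance.

What the generators do **not** emulate: prey motion and evasion, multiple
prey, tracking noise and identity switches, non-Gaussian event features,
failed-hunt kinematics, or any dependence of capture success on the
kinematic features (success is Binomial given attempts). A green test
therefore establishes that each estimator recovers the parameters of its
own generating model at study scale — not that the models are adequate for
real recordings.

## Numerical notes

- The published duration-mean expression multiplies the NB frame-count
  mean by the frame rate; dimensionally this turns frames into
  frames²/s, so the implementation divides by fps instead and documents
  the discrepancy. (With 35.5 s ≈ 14,555 frames at 410 fps, division
  reproduces the printed seconds; multiplication cannot.)
- Where two printed values conflict (evoked LF rate 13.3 in text vs 14.3
  in a caption; PCR CV 0.13/32% with two PCs vs 0.133/31.7% with three),
  the defaults target the text values; nothing in the code depends on the
  caption variants.
- Degenerate inputs: all-zero counts fit cleanly (posterior mass near
  λ = 0); identical mixture points produce boundary/R̂ diagnostics rather
  than a crash; `h = 0` larvae must be excluded by the caller for the
  capture and duration models (the error message says so).
- Real-data quantities that require the original recordings (efficiency
  CDF quantiles, PCR CV = 0.133 / 31.7%, pooled empirical turn-ratios)
  are out of scope and not asserted anywhere.
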