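# Methods

## Model and selection rule

Patient responses on experimental arm `k` are i.i.d. `N(μ_k, v²)` with a
common, known within-arm variance `v²`; higher responses are better.  A
`J`-stage drop-the-losers design is specified by the number of active arms
at each stage `(K₁ > K₂ > … > K_J = 1)` and the per-arm per-stage sample
sizes `(n₁, …, n_J)`.  The stage-`j` sample mean of an active arm is
`Y_kj ~ N(μ_k, σ_j²)` with `σ_j² = v²/n_j`.  At the end of each interim
stage the active arms are ranked by their cumulative MLEs
`X̄_kj = Σ_{i≤j} n_i Y_ki / N_j` and the top `K_{j+1}` continue; ties are
broken in favour of the lower original arm index (a probability-zero event
for continuous data, fixed so that runs are deterministic).  The realized
set of selection inequalities — which arms were dropped at each stage and
which survivor won — is the event `Q`, and the winner's arms means are
relabelled so that index 1 is the selected arm.

A control arm, when simulated, continues to the final stage regardless and
never enters the ranking; its mean is estimable by its ordinary MLE, so
the estimand throughout is the selected arm's mean `μ₁` alone.

Two readings of `Q` are supported through `TrialDesign(q_ordering=...)`.
The default, `membership`, conditions on stage-wise kept/dropped membership
plus the final interim ranking; for a 3:2:1 trial this is exactly three
inequalities (`Y₁₁ ≥ Y₃₁`, `Y₂₁ ≥ Y₃₁`, `X̄₁₂ ≥ X̄₂₂`) and gives
`P(Q) = 1/6` at equal means.  The alternative `full` additionally
conditions on the observed ordering among simultaneously kept arms, which
can bound the final-stage mean from below as well as above (the RB1
machinery then uses a doubly truncated normal mean).  `membership` is the
default because the selection-probability penalty of the conditional
likelihood is built from exactly those three inequalities, and the two
readings' event probabilities (1/6 vs 1/12 at equal means) make
`membership` the one consistent with the trivariate-orthant construction.

## Point estimators

Write `z = Σ_j n_j y_{1j}` for the selected arm's sufficient total.

* **MLE** `X̄_{1J} = z/N_J`.  Positively biased under selection because the
  stage means that won the interim rankings are stochastically too large.
* **Final-stage estimator** `Y_{1J}`: unbiased (stage `J` postdates all
  selection), variance `σ_J²`.
* **RB1** — the conditional expectation `E[Y_{1J} | z, y_{12..1,J−1}, Q]`.
  Multivariate-normal conditioning gives an unrestricted law
  `N(μ̃, σ̃²)` with `μ̃ = (z − Σ_{i=2}^{J−1} n_i y_{1i})/(n₁+n_J)` and
  `σ̃² = v² n₁/(n_J(n₁+n_J))`; the unknown means cancel exactly, which the
  tests verify.  Substituting `Y₁₁ = (z − Σ_{i≥2} n_i y_{1i})/n₁` into each
  selection-stage inequality and solving for `Y_{1J}` yields one upper
  bound per stage,
  `t_j = (z − Σ_{i=j+1}^{J−1} n_i y_{1i} − N_j c_j)/n_J`, where `c_j` is
  the largest cumulative MLE among arms dropped at stage `j`; the binding
  bound is `t = min_j t_j` and RB1 is the truncated-normal mean
  `μ̃ − σ̃ φ(w)/Φ(w)`, `w = (t−μ̃)/σ̃`.  The same closed form holds for
  any `J ≥ 2`; at `J = 2` it reduces to the classical two-stage
  conditionally unbiased estimator.  RB1 is unbiased — also conditionally
  on which arm was selected — and has lower variance than `Y_{1J}` by the
  Rao–Blackwell argument, but it is not the UMVCUE: the conditioning
  statistic is sufficient without being complete.
* **RB2** (three-stage designs) — conditions only on `z` and the stage-two
  rule.  Given `z`, `Y₁₃` is `N(z/N₃, v²(1/n₃ − 1/N₃))`, truncated above at
  `t′ = (z − N₂ X̄₂₂)/n₃`.  The conditioning event is deliberately too
  small, so a small positive bias remains, traded for a substantially lower
  MSE.
* **BC-MLE** (3:2:1 designs) — maximizes the conditional log-likelihood
  `Σ_k log N(s_k; μ_k, v_k) − log P(Q; μ)` over `(μ₁, μ₂, μ₃)`, where the
  data vector is `s = (X̄₁₃, X̄₂₂, Y₃₁)` with variances
  `(v²/N₃, v²/N₂, v²/n₁)`, and `P(Q; μ)` is the positive-orthant
  probability of the trivariate normal selection differences
  `(Y₁₁−Y₃₁, Y₂₁−Y₃₁, X̄₁₂−X̄₂₂)`.

## Numerical choices

* **Truncated-normal means** use `exp(log φ − log Φ)` via
  `scipy.special.log_ndtr`, accurate arbitrarily far into the left tail
  (no asymptotic branch needed); the doubly truncated case works on
  whichever tail is better conditioned.
* **Orthant probabilities** are computed deterministically: Gauss–Legendre
  quadrature (96 nodes) over the first component's surviving probability
  mass, times a closed-form bivariate normal CDF (Owen's T).  Absolute
  accuracy is ~1e-7; the equal-means value matches 1/6 to 4e-7.  Two
  refinements keep the *relative* accuracy good enough for likelihood
  optimization far from the data: the quadrature integrates over upper-tail
  quantiles when the first marginal survival is below one half (stable to
  ~1e-300), and bivariate values below 1e-8 — where the Owen's-T
  representation loses all relative accuracy to cancellation — are
  recomputed by a quantile-substituted tail integral.  SciPy's own
  multivariate normal CDF is quasi-Monte-Carlo with call-to-call jitter, so
  it serves as an independent cross-check in the tests, never as the
  implementation.
* **BC-MLE optimization**: Nelder–Mead from the naive statistics, followed
  by a damped-Newton polish with finite-difference gradients (step 3e-4,
  matched to the quadrature noise floor) and, if the gradient has not
  vanished, a Powell pass and a second start.  The conditional likelihood
  is genuinely bimodal for some "wrong-order" realizations (runner-up
  statistic above the selected arm's): a second mode with a very negative
  `μ̂₁` and a tiny selection probability can dominate, and those
  excursions are part of why the BC-MLE overcorrects on average.  A smooth
  quadratic confinement beyond ±10 marginal standard deviations around the
  data keeps the search where the penalty is numerically meaningful.
  Acceptance requires a finite-difference gradient below 1e-3 (the
  deep-tail noise floor); typical-data fits reach ~1e-6.
* **Profile-likelihood intervals** bisect `Λ(μ₁) = 2[l(μ̂) − max_{μ₂,μ₃}
  l(μ₁,·)]` against the chi-square(1) quantile to 1e-4, warm-starting each
  inner two-parameter maximization from its neighbour.

## Conditional bootstrap

For `rb1`/`rb2` intervals, each bootstrap replicate resamples *every* arm's
stage data with replacement from that arm's own patients and is accepted
only if the resampled cumulative MLEs reproduce the original selection
event (same dropped set at each stage, same winner).  Accepted replicates
are pushed through the estimator's closed form with the truncation bound
recomputed from the resampled competitor statistics, and the equal-tail
percentile interval is read off.  This refresh-everything scheme is the
design choice: freezing the competitor thresholds and the truncation bound
at their originally observed values makes the truncated-mean map saturate
at the frozen bound, collapsing the bootstrap distribution to a fraction of
the estimator's sampling variability (intervals of width ~1.3 where the
sampling distribution supports ~3.3) and destroying coverage; resampling
the competitors restores the correct conditional variability, and the
resulting coverage/width/tail behaviour matches the reference operating
characteristics within Monte-Carlo error.  Acceptance exhaustion (an
acceptance rate so low that the attempt cap is hit) raises an error with
the observed rate; the coverage harness counts and excludes such failures.

## Simulation engine and seeding

`simulate_trial(scenario, i)` draws replicate `i` from an independent
substream keyed by `(seed, i)` (NumPy `SeedSequence` spawning), so any
single replicate is reproducible in isolation; patient-level simulation
stores raw responses only when requested.  The operating-characteristics
harness (`simulate_batch`) instead vectorizes all replicates on a single
seeded stream for throughput — a whole batch is exactly reproducible from
its seed, but its draws differ from the per-replicate path.  Interval
studies, which need patient-level data per trial, use the per-replicate
path.

## What the generator emulates — and what it does not

The synthetic trials are exactly the model above: normal responses, known
common variance, fixed per-stage sample sizes, no early stopping, no
control-based selection, no dropout or missingness.  Passing tests
therefore demonstrate correctness of the estimators *under their own
assumptions*; they say nothing about robustness to unequal variances
(where cumulative-MLE ranking is no longer equivalent to test-statistic
ranking and RB1/RB2 are invalid as stated), to unknown variance, or to
non-normal outcomes.

## Study scales and tolerances

Closed-form estimator summaries use 50,000 replicates (equal-allocation
scenario) and 100,000 (unequal allocation); at those sizes the Monte-Carlo
standard errors are ≈0.003/0.002 on a bias and ≈0.006/0.009 on an MSE.
The BC-MLE, needing a numerical maximization per replicate, is summarized
at 2,000 replicates (bias SE ≈ 0.017).  Interval studies run at 1,000
simulated trials × 500 accepted bootstrap replicates (or one profile
interval) per trial; coverage SE ≈ 0.007.  Statistical assertions in the
test suite use three Monte-Carlo standard errors at the scale actually
run.  One reference value deserves a note: the final-stage estimator's MSE
is *analytically* `σ_J²` (exactly 1.0 and 2.0 in the two null scenarios),
and the tabulated 0.982 for the equal-allocation case sits about three of
its own Monte-Carlo standard errors below that identity; the tests
therefore compare Monte-Carlo MSE estimates at their combined uncertainty
and check the analytic identity directly.

## Known limitations

* The BC-MLE and its profile interval are implemented for 3:2:1 designs
  only; the orthant-probability penalty grows combinatorially with more
  arms.
* RB2 requires a three-stage design.
* The `full` Q-ordering variant affects RB1 conditioning only; the
  selection-probability penalty always uses the membership inequalities.
* Known-variance normal responses throughout; see above.
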