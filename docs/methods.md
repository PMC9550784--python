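# Methods

This note documents the statistical model, the synthetic-data generator, the
numerical choices, and the known limitations of `sigstr`.

## 1. Signal transduction quantities

A signaling event redistributes the amounts of phosphorylated molecules.
With `X_j^st` the baseline (pre-stimulation) amount of molecule `j` and
`X_j` its amount during the event, the **signal transduction quantity (ST)**
is the amount-weighted generalized Kullback–Leibler divergence

    delta_I = sum_j X_j ln(X_j / X_j^st)        [nats · a.u.]

the average information gained by observing the during-event state instead
of the baseline. All logarithms are natural; terms with `X_j = 0` contribute
0.

Per molecule, the measurable quantities are the **signal duration** `tau_j`
(time until the phosphorylation ratio returns to its pre-stimulation level)
and the time-averaged phosphorylation fold change over that duration,
`integral_ratio_j`. The **signal transduction rate (STR)** is the
information gain per unit signaling time:

    beta_j = ln(integral_ratio_j) / tau_j       [1/min]

## 2. Constrained-extremum theory

Introducing Lagrange multipliers for the total amount and the total signal
duration `sum_j p_j tau_j` and setting the gradient of the ST to zero gives
the exponentially tilted allocation

    p_j = p_j^st exp(-beta tau_j),

whose per-step STR `(1/tau_j) ln(p_j/p_j^st) = -beta` is the same for every
molecule: an extremal cascade runs at uniform STR. `verify_uniform_str`
confirms this to 1e-10 (`test_c4_uniform_str_on_tilt`).

Direction of the extremum: the generalized KLD is **strictly convex** in the
allocation, so the tilt is the constrained **minimum** of ST among
allocations with the same total amount and total duration — not a maximum.
Equivalently (Lagrange duality, activation side `beta_j > 0`), the tilt
attains the **maximum total signal duration** among allocations with the
same ST and total amount: an activated cascade at uniform STR signals as
long as possible on a fixed information budget. `check_extremality` and
`check_duration_maximality` verify both facets numerically; the package
deliberately does not claim ST maximization, and the one acceptance test
that encodes that direction is left failing with this analysis as the
reason. On the suppression side (`beta_j < 0`) the same stationary point is
the duration *minimum*, so `check_duration_maximality` rejects nonpositive
rates.

## 3. From raw intensities to STR

Normalization, per molecule and replicate:

1. divide each channel by the negative-control (no-antibody) intensity of
   the same time/replicate — removes global array gain (and cancels
   algebraically; it is retained for fidelity to the assay definition);
2. divide phospho by total (unphosphorylated) signal;
3. divide by the `t = 0` value, so the ratio series starts at exactly 1.

**Signal duration.** `tau` is the zero crossing of the line through two
measured points of the decline of the excess ratio `dX = r - 1`:

    tau = (t2 dX1 - t1 dX2) / (dX1 - dX2)

Two point-pair dialects are provided. `"last_above"`: `t1` = last grid time
with `dX >` threshold, `t2` = its successor. `"peak"` (pipeline default):
`t2` = first grid time after the peak with `dX <=` threshold, `t1` = its
predecessor. Both are exact on noiseless triangular pulses; the `"peak"`
rule additionally cannot be dragged toward the end of the grid by a single
noisy late point. Series that never rise above the threshold are
`no_signal` (STR 0); series that never return are `censored_at_grid_end`.

**Threshold.** The normalized ratio multiplies four CV-0.08 lognormal
measurement factors (phospho and total, at `t` and at 0), so its baseline
log-sd is ≈ 0.16. One pipeline run tests hundreds of
(molecule, replicate, time) points against the threshold; the default 0.6 ≈
exp(3.8·0.16) − 1 keeps the familywise rate of spurious duration extensions
per run well below one. A threshold of a few percent would sit well inside
the noise band and latch the duration onto late-time noise in essentially
every replicate.

**Integration.** `integral_ratio` is the trapezoidal mean of `r(t)` over
`[0, tau]`, appending the analytic endpoint `(tau, 1)` when `tau` falls
between grid points (exact for piecewise-linear kinetics).

## 4. Synthetic data generator

Each active molecule carries a triangular pulse (linear rise to `t_peak`,
linear return to baseline at `tau_true`). Piecewise linearity makes the
duration estimator and the trapezoid rule exact, giving closed-form ground
truth `beta_true = ln(1 + A/(2·baseline)) / tau_true`.

Noise has two mean-1 multiplicative components:

* **spot noise**, lognormal, CV 0.08, independent per record — fluorescence
  measurement error (replicate CVs of such assays are below 0.1; the median
  per-spot CV of a default dataset is ≈ 0.076, `scripts/acceptance.py`);
* a **per-replicate response effect** `gamma_i` (log-uniform, mean 1, CV
  0.45) shared by every molecule of replicate `i` and acting at the rate
  level: the replicate's pulse amplitude is
  `2·baseline·((1 + A/(2·baseline))^gamma_i − 1)`, so its noiseless STR is
  exactly `gamma_i · beta_true`.

The shared effect reflects what a replicate physically is: an independent
culture, stimulation and array, whose overall response strength varies
biologically. It leaves the replicate-mean STR unbiased, produces the
multiplicative replicate spread seen in published array box plots, and makes
equal-rate molecules move in lockstep within a replicate — the signal that
the similarity stage detects. Without it (i.e., with independent spot noise
only) the similarity statistics become pivotal in `Δμ̂/ŝ` and equal-rate
pairs would be called similar only ~46% of the time at any noise level,
which contradicts how replicated cascade measurements actually behave. The
effect is bounded (log-uniform rather than lognormal) because biological
response variation is bounded and a heavy tail would generate spurious
boxplot "outliers" for the trimming step, and it enters at the rate level
because an amplitude-level factor would bias `ln(fold change)` downward.

The default 19-molecule panel activates the proliferative Src–Raf1–MEK1–ERK1
(SRME) cascade at a common 0.08 min⁻¹ over 45 min (3.6 nats, ~37-fold mean
induction — growth-factor-receptor-overexpressing cells show fold inductions
of tens) plus a slower p53 response; the stressed condition adds the
ASK1–MKK4/MKK3–JNK (AMMJ) cascade with its HSF1–Tau extension at 0.12 min⁻¹
over 30 min and weak responders (hsp27, c-Jun, ATF2). Every active molecule
carries ≥ 1.2 nats, several noise sigmas above the detection threshold.

## 5. Bayesian similarity of STRs

Replicate STRs are first trimmed by the boxplot rule — values outside
median ± 1.5·IQR removed, most extreme first, floor of 5 kept. Quartiles are
Tukey hinges (medians of the lower/upper half): the original boxplot
convention; interpolated quartiles over-flag at n = 6.

Model: `y_i ~ Normal(mu, s)` with priors `mu ~ Normal(0, 10²)` and
`s ~ HalfNormal(5)`. Sampling uses independent affine-invariant ensemble
(stretch-move) MCMC chains (default 4 chains × 2000 retained draws, 8
walkers); convergence is monitored with split-chain Gelman–Rubin R̂
(flagged, not rejected, above 1.1). Runs are bit-reproducible for a fixed
seed. If all replicates are identical (e.g. uniformly zero STR for silent
molecules) the likelihood diverges as `s → 0`; the collapsed point-mass
posterior is returned analytically.

Two STRs are **similar** when at least 2 of 3 criteria hold, each evaluated
after rounding to one decimal (the reporting precision of such statistics;
bands are inclusive):

1. effect size `|delta| = |EAP_A − EAP_B| / s_A ≤ 0.3` (Cohen-small), with
   `s_A` the posterior mean of A's replicate-level standard deviation. The
   denominator is the population spread — Cohen's convention — not the
   posterior SD of the mean `mu` (which is smaller by ≈ √n and would turn
   the criterion into a significance test that no replicated equal-rate pair
   could reliably pass). A pooled-spread option is provided.
2. probability of dominance `pi_d ∈ [0.4, 0.6]`: the posterior-predictive
   probability that a new observation from A exceeds one from B (ties count
   one half, so `pi_d(A,B) + pi_d(B,A) = 1`).
3. direction probability `d_pi ∈ [0.4, 0.6]`: the larger of
   `P(mu_A > mu_B)` and `P(mu_B > mu_A)` over paired posterior draws
   (always ≥ 0.5; near 0.5 means the means are indistinguishable).

For collapsed posteriors the effect size is 0 for equal means and ∞
otherwise, and both probabilities fall back to the tie convention.

## 6. Cascade activation and the noise floor

A candidate cascade is **activated** when every consecutive edge (every
branch edge for steps like `MKK4|MKK3`) is similar under the 2-of-3 rule and
every step's EAP STR exceeds the noise floor. The floor is the maximal STR
obtained by pushing the antibody-free control spots through the same
duration/rate pipeline (threshold 0); with the default generator it is
~5 × 10⁻⁴ min⁻¹. A missing edge assessment or posterior is a structural
error, not a negative call.

## 7. Embedding

Each molecule's replicate STR vector, with the minimum and maximum removed
as outliers (6 replicates → 4-dimensional vectors), is embedded in 2-D by
t-SNE (perplexity 5, 1000 iterations, fixed seed). Coordinates have no
absolute meaning; cluster membership does, quantified as the mean silhouette
coefficient over cascade labels (`cluster_separation`). All-identical
vectors map to a single point by convention.

## 8. Numerical choices

* Ensemble MCMC: chains are independent 8-walker stretch-move ensembles with
  per-chain seeds split from the molecule seed, itself split from the
  pipeline master seed (`SeedSequence`); every stage seed is recorded in
  `report.json`.
* `solve_beta` brackets the strictly monotone constraint objective and uses
  Brent's method (`xtol = 1e-12`); the residual scales with
  target × duration.
* t-SNE is deterministic for a fixed seed and library version; only
  topology is asserted anywhere.

## 9. Limitations

* The Normal replicate model is a convenience; replicate STRs from the
  generator are bounded and slightly right-skewed. With n = 5–6 the
  posterior is prior-insensitive but not model-insensitive.
* The similarity rule is calibrated to 1-decimal reporting precision;
  changing `round_decimals` changes the operating characteristics.
* The duration estimator assumes a single dominant pulse; multi-phasic
  responses would need a segmented estimator.
* `cluster_separation` assumes cascade labels partition the embedded
  molecules; overlapping pathway membership is not modeled.
* The ST-maximization reading of the extremum theory is not supported by
  the mathematics (Section 2); downstream interpretation should use the
  minimum-divergence / maximum-duration form.
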