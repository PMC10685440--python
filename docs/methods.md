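# Methods

## Statistical model

The unit of inference is the per-replica binding free energy: each replica
contributes one ΔG value, the arithmetic mean of its frame values over an
analysis window `burn_in_ns < t ≤ t_max_ns` (times carry a 1 ns × 10⁻⁹
comparison tolerance, so "first 5 ns" includes the frame ending exactly at
5 ns). Replicas differ in initial velocities and are modelled as
independent, identically distributed draws from the underlying ΔG
distribution; within-replica frame correlation affects only the precision
of each replica's own frame-mean and is deliberately not propagated into
ensemble-level uncertainties.

All energies are kcal/mol throughout; no unit conversion is performed.

## Estimators

Skewness and excess kurtosis default to the moment-ratio forms
g₁ = m₃/m₂^{3/2} and g₂ = m₄/m₂² − 3 with 1/n-normalized central moments;
`bias_corrected=True` switches to the adjusted G₁/G₂ forms. At the
ensemble sizes where these statistics are decision-relevant (n ≈ 500) the
two conventions differ by O(1/n) ≈ 0.003–0.01, below the two-decimal
precision of study tables, so the choice does not affect conclusions.
Skewness requires n ≥ 3, kurtosis n ≥ 4, and both require nonzero
variance; violations raise explicit undefined-statistic errors rather than
returning NaN.

Confidence intervals use the seeded percentile bootstrap: with-replacement
resamples of size n, interval = the [(1−c)/2, 1−(1−c)/2] empirical
quantiles of the resampled statistic, default 10,000 resamples. The
percentile method (rather than BCa) is the simplest member of the family
and is exactly reproducible from a seed; the test suite pins it against
exhaustive enumeration of all nⁿ resamples at n = 5. Resamples on which a
moment-ratio statistic is undefined (zero variance) are redrawn, capped at
100 × n_boot attempts before erroring. A single "error bar" number always
means the half-width of the 67% percentile interval of the replica-mean,
i.e. roughly one standard error under near-normal sampling; conversions to
standard errors (for z-tests) divide by Φ⁻¹(0.835) ≈ 0.974.

Normality testing uses Shapiro–Wilk (Royston's extension; restricted to
3 ≤ n ≤ 5000, beyond which the caller is directed to the omnibus test) and
the D'Agostino/Pearson K² = Z₁² + Z₂², combining D'Agostino's skewness
transform with the Anscombe–Glynn kurtosis transform and requiring n ≥ 20
for the transforms' validity; both delegate to SciPy's implementations
behind this package's contract checks. The Q-Q analysis standardizes the
sample by its own mean and SD, pairs order statistics with standard-normal
quantiles at plotting positions (i − 0.5)/n (Blom's (i − 3/8)/(n + 1/4)
available by flag), and builds the confidence envelope as the pointwise
percentile band of similarly standardized order statistics over 10,000
seeded normal simulations of the same n. A pointwise band was chosen over
a simultaneous one because it is assumption-light and matches how such
envelopes are usually drawn; its per-point (not family-wise) coverage is
what the calibration test checks.

## Budget protocols

For a budget B the candidate allocations are k replicas × t ns with
t = B/k floored to the frame grid and clipped to the available trajectory
length. Defaults `min_replicas = 2` and `min_duration_ns = 2` encode two
field rules: a single trajectory cannot quantify its own uncertainty, and
~1-ns production runs are too short to converge — under a 60-ns budget
this leaves exactly {6×10, 12×5, 20×3, 30×2}.

A protocol is scored by drawing k replicas without replacement, truncating
to the first t ns, and taking the replica-mean; the error bar is the 67%
bootstrap half-width over the k per-replica values (replica-level, never
frame-level, bootstrap). The default is a single seeded subset draw —
mirroring how one such comparison is done in practice — with
`n_subset_draws > 1` available to average over subset selection and expose
its variability. The recommendation logic compares each protocol to a
consensus (the supplied full-data estimate, else the largest-k·t protocol)
by two-sided z-tests on the difference, flags significant discrepancies,
and among the indistinguishable protocols picks maximal k, tie-broken by
smaller t. When the consensus is an external full-data value its own
uncertainty defaults to zero unless supplied, which makes the test
slightly conservative toward flagging.

## Adaptive schedules

The stopping rule starts at the protocol minimum (10 replicas
ESMACS-style, 3 TIES-style), evaluates the error bar of the mean ΔG, and
adds `batch_size` (default 5) replicas until error_bar ≤ threshold
(default 0.5 kcal/mol), the cap `max_n` (default 50) is reached, or the
replica source is exhausted. Stopping is only evaluated at batch
boundaries because replicas are scheduled in batches on real resources.
The rule is the plain sequential threshold: repeatedly checking a noisy
error bar stops, on average, slightly before the fixed-n budget that
would achieve the same precision (optional-stopping bias); this is a
property of the procedure itself and is documented rather than corrected.
For iid replicas with spread σ the median stopping time scales as
(σ/threshold)², which the tests verify across σ ∈ {1, 2, 4}.

## Synthetic ensembles

The generator emulates the statistical structure of replica ensembles, not
their physics. Marginal families — Gaussian, Azzalini skew-normal,
location-scale Student-t, finite Gaussian mixtures — span the deviations
reported for real free-energy distributions: skew of either sign, excess
kurtosis, heavy tails, multimodality. Population moments are closed-form
(`analytic_moments`), with nonexistent Student-t moments returned as an
explicit `None`.

Three structural features layer on top of the marginal:

- **Within-replica correlation** (`ar1_rho`): a stationary AR(1) driver
  with exact N(0,1) marginal mapped through a Gaussian copula
  (Φ, then the target quantile function). The marginal is preserved
  exactly — for mixtures up to a dense monotone interpolation of the
  inverse CDF — while the lag-1 correlation of the transformed series
  equals ρ exactly only in the Gaussian case and is mildly attenuated
  otherwise; tests bound the attenuation. Published ensemble studies do
  not report frame-correlation magnitudes, so the default is ρ = 0 and any
  nonzero choice is the user's.
- **Between-replica spread** (`between_replica_sd`): a persistent Gaussian
  offset per replica, drawn once and added to every frame — replicas
  started from different initial conditions settling at different levels.
  Cumulants add under this convolution, so `analytic_moments` dilutes
  skewness by σ³/(σ² + b²)^{3/2} and excess kurtosis by σ⁴/(σ² + b²)²
  exactly. This is the regime that makes replica count more valuable than
  trajectory length: with iid frames and no between-replica component,
  every equal-budget protocol has identical precision, and the budget
  comparison would be vacuous.
- **Per-replica modes** (`per_replica_modes`): each replica is pinned to
  one mixture component for its entire trajectory, emulating replicas
  trapped in distinct conformational basins; the pooled cross-replica
  marginal is still the mixture.

Reproducibility: one master seed, per-replica substreams spawned
deterministically (NumPy `SeedSequence`), so identical specs are
bit-identical and an N-replica ensemble is a prefix of a larger one with
the same seed — which also makes the on-demand replica source used by the
adaptive runner consistent with `generate_ensemble`.

What passing tests on these ensembles do **not** show: correctness of any
energy function, force field or sampling protocol; behavior under
non-stationary drift (equilibration transients) beyond the drift fixture
used to probe duration sensitivity; or realistic frame-correlation
structure. The synthetic marginals are ground truth for the *estimators*,
not stand-ins for any particular molecular system's data.

## Study sizes and numerical choices

Default problem sizes mirror field practice: 25 replicas × 4 ns ensembles
(0.1-ns frames) as the generator default, 500-replica single-frame
ensembles where the marginal must be inherited exactly by the per-replica
values (frame-averaging dilutes frame-level non-normality by the central
limit theorem — visible in the demo campaign, where only replica-level
structure survives aggregation). Simulation-based tests use 10²–10³
repetitions, chosen to keep Monte-Carlo noise a factor of ~3 below each
assertion's tolerance. Report rendering rounds moments to 2 decimals and
p-values to 3 significant digits; the JSON document keeps full precision,
and the reporter never recomputes a statistic. Per-frame CSV output
prints floats with `%.17g` and is parsed back with round-trip precision,
making the per-frame dialect a lossless interchange format.

## Known limitations

- Ensemble SEMs ignore within-replica autocorrelation (no effective-
  sample-size correction); the replica level is where inference happens.
- No variance decomposition between- vs within-replica is reported.
- The Q-Q envelope is pointwise, not simultaneous.
- The externally deposited 500-replica study tables are not redistributed
  here; the loader's `per_replica` dialect plus `--col-map` is the
  documented adapter for them.
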