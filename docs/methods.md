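# Methods

This note documents the models, their assumptions, the numerical choices,
and what the synthetic data can and cannot establish.

## The two-state switching model

States: anoikis-sensitive (S) and anoikis-resistant (R). Switching happens
at division only: each daughter of an S parent is R with probability
`k_on`, each daughter of an R parent is S with probability `k_off`, both
per generation. The resistant state's memory is the mean residence time
`M = 1/k_off` generations (geometric residence); equilibrium resistant
frequency is `f_eq = k_on/(k_on+k_off)`; the single-lineage state
autocorrelation decays per generation by `λ = 1 − k_on − k_off`.

Suspension assay of duration `T` hours: sensitive cells are dead by the
endpoint (default `all_dead_at_T`; an exponential per-hour hazard `δ` is
available for sensitivity analysis), resistant cells proliferate with
doubling time `T_d_susp`, growth rate `γ = ln 2 / T_d_susp`. The survival
balance `f·e^(γT) = S̄` therefore links the plated resistant fraction to
the mean observed survival; the all-dead default is what makes this
relation exact, which is why it is the default. Survival fractions may
exceed 1 (net growth in suspension) and are never clipped.

Key parameter defaults (changeable everywhere):

| parameter | default | meaning |
|---|---|---|
| `S̄` | 0.9 | mean 24-h suspension survival used in the balance |
| `T` | 24 h | assay duration |
| `T_d_susp` | 100 h | resistant doubling time in suspension |
| `T_d_2D` | 38 h | attached doubling time (generation↔hour conversion) |
| `M` | 10.5 gen | resistant-state memory (10–11 range) |
| `G` | 20 | expansion generations before the first assay |
| `N0` | 250,000 | cells plated per assay |
| `n_clones` | 60 | clones per experiment |

With these defaults `f_eq ≈ 0.762`, `k_off = 1/10.5 ≈ 0.095`,
`k_on ≈ 0.305`, `λ ≈ 0.60`.

## Protocol simulation

Attached expansion is deterministic doubling with stochastic daughter-state
switching: the object of the fluctuation test is switching noise, not
demographic noise, so division itself is noiseless by default (a
`division_prob < 1` stochastic-division mode exists, aggregate mode only).
Two equivalent representations are provided:

* **aggregate** (default): the pair `(n_S, n_R)` is propagated with two
  binomial draws per generation. Because daughters switch independently,
  this is exact in distribution and handles `G = 20` (≈10⁶ cells) and
  `N0 = 250,000` instantly.
* **exact**: an explicit per-cell state array, practical to `G ≈ 12`,
  kept as an independent implementation; a two-sample KS test across seeds
  checks the two modes agree in distribution.

Plating draws `N0` cells without replacement (hypergeometric). In exact
mode a clone smaller than `N0` is an error; aggregate mode plates the whole
clone in that case. The assay grows each plated resistant cell as a Yule
(pure-birth) process — family size at `T` is geometric with mean
`e^(γT)` — so the clone's live count is shifted negative binomial; no
switching occurs during the 24-h assay by default (less than one attached
generation; a plating-time switching step is toggleable).

All randomness in an experiment flows from a single `numpy` generator
seeded by one integer; every result object echoes model, protocol and seed.

### Verification

Two independent oracles back the simulator in the test suite: exact
enumeration (dynamic programming over the binomial switching convolution,
hypergeometric plating, closed-form Yule moments) for small instances, and
an exact moment recursion
(`m' = 2λm + 2Nk_on`,
`v' = 2k_off(1−k_off)m + 2k_on(1−k_on)(N−m) + 4λ²v`) that scales to the
full protocol. Monte Carlo agrees with both within Monte Carlo error.

### The prediction and its edge

Under the defaults the predicted interclonal CV is ≈0.0015 at
`T_d = 100 h` and stays below 0.01 over the whole grid 38–200 h, far below
the observed 0.25–0.3 — the quantitative basis for rejecting the two-state
model. One honest caveat: at the grid edge `T_d = 38 h` the full-protocol
prediction is CV ≈ 0.0088 (the moment recursion confirms the Monte Carlo),
so dividing the observed lower bound 0.25 by the prediction gives ≈28.5
rather than ≥30 at that single point; against the observed upper value 0.3,
or at any `T_d ≥ 50 h`, the 30-fold separation holds with a wide margin.
The corresponding acceptance test asserts the ≥30 bound as stated and is
expected to fail at exactly this grid point; it is left failing rather than
weakened.

## Fluctuation statistics

* **CV** uses the sample SD (n−1 denominator) over the mean; the
  convention is stated because cohort sizes are small.
* **Bootstrap CI**: percentile bootstrap over clone resampling is the
  default and is what the "CV ± half-width" reporting format uses. On the
  skewed sampling distribution of the CV at n = 60 the percentile interval
  undercovers mildly (measured ≈0.885 empirical coverage at nominal 0.95
  over 1,000 synthetic tables); the BCa interval (`method="bca"`, via
  scipy) restores near-nominal coverage (≈0.906) and is the one held to
  the 0.90–0.97 band in the coverage tests.
* **Inter-passage regression**: OLS slope and Pearson r with two-sided p,
  per first-vs-later passage pair; no multiple-testing correction across
  the two comparisons.
* **Growth rates**: per-clone `ln(N_t/N_0)/T`; clones with zero survivors
  are a separate −∞ class excluded from moments; the "doubling" class is
  rate ≥ ln2/45 per hour; the cohort CV is reported as |SD/mean| since the
  mean is typically negative.

## Memory-decay model

Reversion of resistance during stress-free attached growth follows
geometric decay `f(g) = f0(1−k_off)^g` (with re-induction, geometric
relaxation to `f_eq`). Fitting is linear least squares of `log f` on `g` —
exact on noiseless curves; non-positive values are masked with a warning;
two-point fits are flagged underdetermined. `generations_to_threshold`
inverts the decay law against a user-supplied parental survival threshold
(not hard-coded: parental levels are experiment-specific).

A deliberate, documented tension is asserted in the tests: the `k_off`
implied by full reversion in 8–14 generations is incompatible with an
equilibrium resistant fraction of 0.76 under the same two-state parameters
(with re-induction the resistant fraction can never decay below `f_eq`).
The same minimal model cannot produce both the survival balance and the
reversion curves — a second, independent argument for a continuum of
states.

## Heritable-continuum generator

Each clone carries a latent suspension growth rate
`g_i ~ Normal(μ_g, σ_g²)` per hour; across passages the latent value
follows an AR(1) with coefficient `ρ` (passage labels `P<k>` contribute
`|k_b−k_a|` AR steps); observed survival is `exp(g_i·T)` times unit-mean
lognormal measurement noise with CV `meas_cv`. Counts are emitted as
`n_live = round(survival·N0)` so tables are schema-consistent.

Preset `ov90-clones` pins `μ_g = −0.004 /hr`, `σ_g = 0.012 /hr` (the
cohort's growth-rate mean and 300 % CV taken as direct generator
parameters), `ρ = 0` (no passage-to-passage correlation), and
`meas_cv = 0.05`, a modest technical-noise term chosen once, below the
population-level replicate CV because that value also absorbs biological
batch variation. The implied survival distribution is lognormal with
analytic mean ≈0.947 and CV ≈0.299 (`continuum_survival_moments`).

Two calibration facts follow from the arithmetic, not from tuning:
(1) the survival CV cannot be pushed below ≈0.294 while keeping
`σ_g = 0.012` — measurement noise only adds variance; (2) by Jensen's
inequality any latent distribution with mean growth −0.004/hr forces mean
survival ≥ e^(−0.096) ≈ 0.908, so "mean survival 0.90" and "mean growth
−0.004/hr" cannot hold simultaneously and exactly in any such model; the
generator privileges the growth-rate moments and lands at mean ≈0.95,
CV ≈0.30 — within the observed CVs' own confidence half-width.

Preset `ov90-parental` emits population replicates (mean 0.9, noise CV
0.11, no clonal term). Preset `two-state-default` records the switching
model's study parameterization. Presets are versioned YAML files shipped
in the package, not code constants.

### What the synthetic data does not show

The generator reproduces summary moments (means, CVs, growth-rate
structure, passage independence), not the unknown shape of the real clone
distribution — only moments were reported, and Normal-on-growth-rate is an
assumption. Passing tests therefore establish that the pipeline measures
what it claims on data with the reported structure; they are not evidence
about un-modelled features of real assays (counting error structure,
plating-density effects, aggregate formation in suspension).

## Numerical and design choices

* Infeasible parameter combinations (implied `f > 1`, `k_on > 1`,
  `f_eq = 1` with finite memory) raise typed errors; nothing is silently
  clamped.
* `T_d = ∞` is a valid no-growth limit (`γ = 0`).
* Degenerate statistics (zero mean for a CV, zero variance for a
  correlation, all-zero survivals) raise with explicit messages; constant
  bootstrap input returns a zero-width interval rather than resampling.
* Determinism: every stochastic routine takes a seed or Generator;
  sub-seeds are drawn from one parent generator per run, all below 2³¹.
* Problem sizes in the shipped tests (200 replicate experiments per grid
  point, 1,000 tables in the coverage study, 100–500 seed averages) were
  chosen so Monte Carlo error sits well inside each asserted tolerance
  while the whole suite stays in the tens of seconds.
* The CLI validates YAML/JSON configs against a strict schema (unknown
  keys rejected), logs to stderr only, and uses exit codes 0/2/3 for
  success/config error/data error.

## Known limitations

* No spatial structure, aggregates/spheroids, drug response or in-vivo
  dynamics; single-phenotype-axis models only.
* The reversion fit assumes a single geometric decay rate; multi-state or
  age-dependent memory would need a different model.
* The continuum generator's AR(1)-across-passages is phenomenological; it
  is not a mechanistic model of chromatin or transcriptional state.
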