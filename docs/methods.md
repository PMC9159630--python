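# Methods

This note records the statistical models, algorithmic conventions and
numerical choices behind the package, including the points where the
design was genuinely open and a choice had to be made.

## Single trials

A trial is a 2×2 table (e₀, n₀, e₁, n₁). Modifications (f₀, f₁) range
over −eₖ ≤ fₖ ≤ nₖ − eₖ, optionally restricted per group to increases,
decreases, or nothing (clinicians may judge missed events far more
plausible than spurious ones, or vice versa).

Five association methods produce p(f₀, f₁):

* **Fisher's exact test** — two-sided conditional p under the
  hypergeometric null, probability-mass rule: the sum of the
  probabilities of all tables (margins fixed) no more probable than the
  observed one. A relative slack of 1 + 1e−7 guards the ≤ comparison
  against floating-point ties, the convention of the major statistical
  environments; agreement with `scipy.stats.fisher_exact` and with a
  direct enumeration oracle is asserted in the tests to 1e−12. The
  enumeration is implemented in-package (vectorised over the shared
  hypergeometric support) so that full modification landscapes are cheap.
* **Pearson chi-squared** — X² = N(|ad−bc| − c_y)²/(r₁r₂c₁c₂) on 1 df,
  with the Yates term c_y = N/2 (capped at |ad−bc|) applied by default,
  matching the common 2×2 default of standard software; a flag disables
  it. A zero margin leaves the statistic undefined: p = 1 with a warning.
* **Wald tests** of the log odds ratio, log relative risk, and risk
  difference, with the textbook large-sample standard errors. If any of
  the four cells is zero, 0.5 is added to all four cells of that table
  (per table, re-evaluated after every modification), which keeps
  estimate and SE finite. Two-sided p = 2Φ(−|y−θ₀|/s); the one-sided
  p is exactly half of that. Note this one-sided form is
  direction-agnostic (always the favourable tail); it is implemented
  verbatim and differs from a signed one-sided test.

**Significance is strict**: significant iff p < α; p = α counts as
non-significant.

Two search strategies share one vectorised p-value kernel and therefore
agree exactly: `fi_exhaustive` evaluates every legal modification
(retaining the landscape for plots; grids above 10⁶ cells are refused —
a trial with 1000 patients per arm already yields about a million
modifications — with a pointer to the search), and `fi_search`
enumerates shells |f₀|+|f₁| = 1, 2, … until the first flip. Within a
shell, modifications are ordered f₀ ascending then f₁ ascending, making
the reported set of minimal modifications deterministic.

**Alpha sweeps** evaluate FI over an equally spaced grid (default 100
levels from 0.005 to 0.05, the range spanned by the conventional and the
stricter reproducibility-motivated thresholds). The average FI is the
arithmetic mean over levels where the FI is defined; the number of NA
levels is reported alongside rather than folded into the mean. The sweep
only needs each shell's running minimum and maximum p, so shells are
evaluated once and shared across all levels; monotonicity of FI(α) on
each side of p(0,0) follows directly from that representation and is
asserted on random tables.

FQ uses the total sample size n₀+n₁ even when modifications are
restricted to one group (the restricted-denominator alternative is
arguable but would make FQ incomparable across constraint choices).

## Pairwise meta-analyses

The conventional two-level normal model: yᵢ ~ N(θᵢ, sᵢ²) within studies
(sᵢ treated as known), θᵢ ~ N(θ, τ²) across studies. Per-study effects
come from the single-trial estimators, the continuity correction firing
study by study; double-zero studies are retained with correction rather
than dropped (the pooling layer is silent about them either way, and
retention mirrors the default path of the standard tooling).

τ² estimators: DerSimonian–Laird moments (truncated at zero — the
truncation is explicit) and REML via the standard fixed-point iteration
(tolerance 1e−8, at most 100 iterations, DL fallback with a warning on
non-convergence; 500-replicate simulations at τ² = 0.25 recover the
truth within Monte-Carlo error). A "fixed" option forces τ² = 0.

Pooling uses weights wᵢ = 1/(sᵢ² + τ̂²), θ̂ = Σwᵢyᵢ/Σwᵢ, and either the
normal interval θ̂ ± z₁₋α/₂ (Σwᵢ)^(−1/2) or the HKSJ interval
θ̂ ± t_{N−1,1−α/2} · √[Σwᵢ(yᵢ−θ̂)²/((N−1)Σwᵢ)]. The HKSJ scale is used
exactly as written, without the truncation variant that floors it at the
normal-interval width; it collapses to zero width on perfectly
homogeneous inputs. Defaults are OR / DL / z. Agreement of the DL + z
path with statsmodels' `combine_effects` is asserted to 1e−6 (the
reference does not truncate τ², so the comparison is made on datasets
where the estimate is positive).

### Greedy fragility search

Exhaustive search over modification sequences needs up to (2N)^FI
refits, so the FI of an (N)MA is obtained greedily. Significance is
judged by the CI against the null. At each iteration the admissible
single-event changes (≤ 2N of them: one event removed from group 1 or
added to group 0 per study for a leftward push, mirrored rightward) are
each applied to a copy of the current data, the meta-analysis is refit —
**τ² re-estimated at every candidate refit**, since each candidate is a
full separate analysis — and the candidate moving the watched CI bound
furthest toward the flip is kept (the bound that must cross the null:
the lower bound when pushing a significant above-null result left, the
upper bound when pushing a non-significant result toward left-side
significance, and mirror images). Ties keep the first candidate in the
deterministic order: lowest study id, group 1 before group 0 within a
study.

A significant original result determines its own direction. A
non-significant one can reach significance on either side; `mod_dir`
selects left, right, the side of the point estimate ("one"; a point
estimate exactly at the null defaults to right with a warning), or both.
"Both" runs the two directions independently from the original data and
takes the smaller FI; `fits_performed` reports the winning run's refits
(bounded by 2N×FI), `fits_total` the sum over runs.

Termination is guaranteed by an iteration cap defaulting to the total
sample size; hitting it, or exhausting candidates, yields FI = NA with a
diagnostic. On exhaustively searchable instances (≤ 3 studies, arms of
≤ 6) the greedy FI is compared against a breadth-first-search optimum:
it is never smaller, and is exact on most instances; the gap
distribution is exercised in the tests.

## Network meta-analyses

Arm-level data (sid, tid, e, n; treatments and studies indexed by
natural numbers from 1) are expanded to all within-study pairwise
contrasts. Zero-cell handling mirrors the standard arm-to-contrast
conventions: by default 0.5 is added to all four cells of a contrast
containing a zero; `allincr` extends the correction network-wide once
any study has a zero; `addincr` always corrects; two-arm double-zero
studies are uninformative for OR/RR and are dropped unless
`allstudies`. For studies with p > 2 arms the p(p−1)/2 contrast
variances are re-weighted by the graph-theoretical variance
decomposition: the study's variance matrix V maps to its Laplacian
L = pinv(−CVC/2) (C the centring matrix), whose off-diagonal entries are
the adjusted edge weights — for consistent variances this carries
exactly the information of the joint arm-based model, and for two-arm
studies it is the identity. Networks must be connected (components are
named in the error) and every study must contribute ≥ 2 arms.

The fixed-effect fit is weighted least squares on the treatment graph
via the Moore–Penrose inverse of the weighted Laplacian; all K(K−1)/2
comparisons come from the node potentials, so antisymmetry and triple
consistency θ̂_AB + θ̂_BC + θ̂_CA = 0 hold identically, and estimates do
not depend on any reference-treatment choice. Variances are resistance
distances; CIs are normal-based.

The common between-study variance uses a generalized DerSimonian–Laird
moment estimator: with Q the fixed-effect weighted residual sum,
df = Σ(pᵢ−1) − (K−1), and tr(PG) the trace of the residual-forming
matrix against the within-study heterogeneity structure (unit variance
per contrast, covariance ½ for contrasts sharing an arm — the standard
consistency assumption), τ̂² = max{0, (Q−df)/tr(PG)}. On a network of
two-arm studies of a single comparison this reduces algebraically to the
pairwise DL estimator, which the tests assert; the estimate is then
added to every raw contrast variance and the multi-arm adjustment and
WLS are redone. The exact moment weighting inside other NMA software
varies; this construction was chosen for its closed form and its exact
pairwise reduction. The fixed-effect fit is validated against an
independent GLS formulation on baseline-arm contrasts with full
within-study covariance (an entirely different computational route) to
1e−6 on the bundled COPD network and to 1e−8 on random networks.

Per-comparison fragility restricts candidate modifications to arms of
the two compared treatments, in any study containing them — changes
there act most directly on that comparison and keep the search to
≤ 2 × (arms of A and B) × FI refits — but the **full network is refit
after every candidate change**, so indirect evidence is always
propagated. An FI of NA therefore means only that no flip is achievable
within those two treatments' arms; modifications elsewhere might still
flip the comparison, and NA values must be read in that restricted
sense. FQ has two denominators: the pair's sample size n_AB (ranges over
(0,100], comparable across pairs) and the whole network's n_NMA (bounded
by n_AB/n_NMA, reported for completeness). Comparisons are assessed
independently from the original data, so results are order-independent
and trivially parallelisable.

## Synthetic data

The generators emulate the three input schemas under the same model the
engines assume: binomial arm events on a logit scale, control-arm risk
fixed at the configured baseline, per-study log OR drawn N(θ, τ²) (for
networks, independent N(0, τ²/2) perturbations per arm, giving every
contrast heterogeneity variance τ²). Defaults — arm sizes uniform on
50–300, baseline risk 0.15, OR 0.8, τ² = 0.1 — represent a typical
moderately sized trial collection with a modest effect and mild
heterogeneity, the regime of the bundled clinical examples. One
`numpy.random.Generator` seeded from the `seed` argument drives
everything; a seed fully determines the output.

What the generator does **not** emulate: publication bias and
small-study effects, very rare events (double-zero-heavy collections),
between-study variation in baseline risk, correlation between arm size
and effect, multi-arm trials in the pairwise schemas, and
informative missingness. Passing tests on synthetic data therefore
demonstrate internal correctness of the estimators and searches under
the stated model, not robustness to those real-data features.

## Numerical choices and problem sizes

* Fisher probability-mass comparisons use relative slack 1 + 1e−7;
  p-values are never rounded internally (display rounding is the
  reporting layer's job).
* τ̂² truncation at zero is applied in DL, REML, and the network moment
  estimator.
* Exhaustive landscapes refuse more than 10⁶ cells by default.
* Greedy runs cap iterations at the total sample size.
* The randomized test-suite sizes — 300 tables per method for the
  search/exhaustive equivalence, 50 tables × 20 levels for monotonicity,
  50 synthetic MAs for the work bound, 30 tiny MAs for the optimality
  comparison, 20 two-treatment networks, 50 reference comparisons, 500
  recovery replicates at N = 30 — were chosen so the whole suite runs in
  well under a minute on one core while keeping Monte-Carlo error small
  relative to the asserted tolerances.

## Known limitations

* The greedy FI is an upper bound on the true minimal modification count
  for (N)MAs; the exhaustive optimum is only computed as a test oracle
  at toy scale.
* The one-sided Wald p is the printed direction-agnostic form, not a
  signed test.
* Survival, continuous, and regression-adjusted outcomes are out of
  scope, as are Bayesian network models, inconsistency diagnostics, and
  treatment ranking.
* FI comparisons across methods invite "fragility-hacking"; users should
  derive the FI with the analysis method pre-specified in the study
  protocol.
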