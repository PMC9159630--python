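# fragility

Fragility assessment of clinical results with binary outcomes: how many
individual patients' outcomes would have to change for a result to cross
the statistical-significance boundary?

Given a two-arm trial reported as a 2×2 table — events *e₀* of *n₀* in
group 0, *e₁* of *n₁* in group 1 — an *event status modification*
(*f₀*, *f₁*) turns *fₖ* non-events into events in group *k* (negative
values the reverse), leaving sample sizes fixed. The **fragility index**
is the smallest total change that flips the test decision at level α:

    FI = min { |f0| + |f1| : p(f0, f1) ≥ α }   if p(0,0) < α,

and with the inequalities reversed when the original result is
non-significant. FI = NA when no legal modification flips the result.
The **fragility quotient** FQ = FI / (n₀+n₁) × 100% makes trials of
different sizes comparable, and the **average FI** summarises FI(α) over
a grid of significance levels. Restricted indices FI₀ and FI₁ confine
the changes to one group (1 ≤ FI ≤ min{FI₀, FI₁}).

The package computes these measures for

* **single trials** — five association methods (Fisher's exact test,
  Pearson chi-squared, and Wald tests of the log OR, log RR, and risk
  difference, with 0.5 continuity correction for zero cells), by
  exhaustive landscape enumeration or an equivalent shell search;
* **pairwise meta-analyses** — inverse-variance pooling with
  DerSimonian–Laird or REML heterogeneity and normal or
  Hartung–Knapp–Sidik–Jonkman intervals, with the FI obtained by a greedy
  CI-driven search needing at most 2N×FI refits;
* **network meta-analyses** — the frequentist graph-theoretical model
  (weighted least squares on the treatment network, multi-arm variance
  adjustment, a common method-of-moments τ²), with a per-comparison FI
  whose modifications are restricted to the two compared treatments.

It is aimed at biostatisticians and systematic reviewers who want to
report fragility alongside p-values and confidence intervals, and ships
plotting helpers (significance landscapes, FI-versus-α step plots,
modification trajectories, FI/FQ distributions), readers/writers for the
three CSV schemas, seeded synthetic-data generators, and a CLI.

## Worked example

```python
from fragility import TwoByTwoTable, TestSpec, fi_search, fi_nma, load_example

trial = TwoByTwoTable(e0=7, n0=107, e1=12, n1=105)   # first bundled trial
res = fi_search(trial, TestSpec("fisher"), alpha=0.05)
print(res.p0, res.fi, res.fi0, res.fi1, round(res.fq, 2), res.direction)
# 0.23755805145777997 3 3 4 1.42 nonsig_to_sig

copd = load_example("copd")          # complete 3-study, 4-treatment network
net = fi_nma(copd, random=True)
print({(p.tid1, p.tid2): p.fi for p in net.pairs})
# {(2, 1): 4, (3, 1): 2, (4, 1): 3, (3, 2): 6, (4, 2): 6, (4, 3): 7}
```

The trial's Fisher p-value is 0.238, so the result is non-significant at
α = 0.05; changing three patients' outcomes (all in group 0, or the
reported mixed patterns) would make it significant — 1.42 % of the 212
participants. In the chronic-obstructive-pulmonary-disease network, the
salmeterol-versus-placebo comparison (3 vs 1) is the most fragile: two
event changes in those arms flip it to significance.

The same analyses are available from the shell:

```bash
fragility study --e0 7 --n0 107 --e1 12 --n1 105 --out study.json
fragility nma src/fragility/datasets/copd.csv --out nma.json
fragility plot --kind p-grid --e0 7 --n0 107 --e1 12 --n1 105 --out landscape.png
```

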