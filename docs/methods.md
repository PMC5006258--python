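# Methods

## Outcome model

Each participant's visit outcome at weeks 4, 8 and 12 is one of three
mutually exclusive categories: quit study drug; on drug with an
efficacious response; on drug without one. Efficacy is a reduction of at
least 50 % from the baseline pain score — the boundary is inclusive, so a
follow-up score of exactly half of baseline counts as efficacious.
Quitting is absorbing: after a quit, every later visit is quit. Pain
scores are accepted as real numbers; the Likert scale's integer range is
not enforced (an optional valid range produces warnings only), and a
non-positive baseline is rejected because the reduction fraction would be
undefined. Quit status is an explicit flag in the data, never inferred
from a missing score: a visit with neither score nor flag is simply not
yet observed. A record whose later visit is observed while an earlier one
is absent warns rather than fails — multisite data entry is asynchronous.

The 12-week outcome of arm *a* is multinomial with simplex parameter
θ_a under a Dirichlet(1/3, 1/3, 1/3) prior (a uniform-information prior
carrying total weight 1). The arm utility is U_a = w·θ_{a,2} + (1 −
θ_{a,1}) with w = 0.75, ranging over [0, 1.75]; w is configurable
(`utility_weight`).

## Interim analysis

At an interim, patients split into: complete (12-week outcome observed),
incomplete (a 4- and/or 8-week outcome only), and uninformative (no
post-baseline visit yet) — the last group is excluded entirely.
Incomplete non-quitters are bridged to 12 weeks by conditional transition
models: for each (arm, interim week) pair, the 12-week category given
early efficacy has prior Dirichlet(1, 7, 2) (prior mean rates 10/70/20 %)
and given early non-efficacy Dirichlet(1, 2, 7); each prior carries
weight equivalent to ten patients and is updated with the complete
patients observed at that (arm, week) in the matching state. A patient
observed at both interim weeks contributes to both models; when both
interim outcomes are available for an incomplete patient, the latest
(week-8) model is the one used for imputation. An incomplete patient
whose latest observed outcome is quit is imputed as quit with certainty.

The posterior quantities are computed by Monte Carlo with multiple
imputation: m = 20 completions; for each, per-patient final categories
are drawn from the posterior predictive (a Dirichlet draw of a
probability triple, then a categorical draw), arm counts are added to the
outcome prior, and ⌈n_draws/m⌉ utility draws per arm are taken (n_draws =
10,000 by default). Draws are pooled across completions, so the reported
V(U_a) includes between-imputation variance. P_a^max is the fraction of
pooled draw indices on which arm *a* attains the maximum utility; exact
ties split uniformly at random (they have probability zero for
non-degenerate posteriors but matter for hand-built degenerate inputs).
With fully complete data the procedure is numerically invariant to m and
to the imputation stage (no imputation randomness is consumed), which the
tests assert exactly. Every summary records the seed and draw count used.

## Adaptive allocation and stopping

After the burn-in, allocation is proportional to
I_a = √(P_a^max · V(U_a)/(n_a + 1)) over the open arms; n_a is the number
of records entering the interim for arm *a*. An arm with P_a^max ≤ 0.01
(inclusive) becomes a permanent loser with zero allocation; the trial
stops early when the largest P_a^max ≥ 0.925 (inclusive). If every open
arm has zero information — possible only for degenerate posteriors —
allocation falls back to equal shares over open arms. All arms becoming
losers is arithmetically impossible with four arms (P^max sums to 1), and
is surfaced as an explicit error rather than a silent fallback.

The allocation table starts with a balanced, uniformly shuffled burn-in
block (80 slots, 20 per arm) plus 20 spare slots, also balanced (5 per
arm, shuffled separately) — the spares keep clinics enrolling while an
adapted table is prepared; their composition preserves the burn-in's
equal-allocation intent and is configurable. Each adaptation deletes all
unassigned slots and appends a block of 100 slots whose arms are drawn
independently per slot from q (not forced to exact proportions). Assigned
slots are never touched, keep their original indices, and new indices
continue past the largest ever issued, so a slot index is a stable
audit key. Assignment takes the first unassigned slot (optionally within
a stratum; stratification defaults off); an exhausted table raises an
explicit error — the signal that the spare buffer was undersized.

## The simulator

Synthetic patients follow the generative chain the interim model targets:
week-4 category from a per-arm triple p4; weeks 8 and 12 from per-arm
transition triples t_eff / t_noeff conditional on the current non-quit
state (optionally different for the 8→12 step); quit absorbing. The
implied 12-week marginal is available in closed form (chain product) and
anchors the generator's distributional tests. Raw baseline/follow-up
pain scores consistent with each category are synthesized (baseline an
integer in 4–10; efficacious follow-ups uniform in [0, b/2), others in
(b/2, b]) so simulated cohorts round-trip through the CSV reader and
classifier.

Accrual is deterministic at `accrual_rate` patients/week (default 4/week,
≈ 400 patients over two years). The first interim runs at the calendar
week of the 80th enrollment; subsequent interims every 13 weeks from that
anchor, while enrollment is open. An interim sees an outcome only if its
visit week has elapsed for that patient; patients enrolling at or before
the interim week draw from the old table (the spare buffer's role), with
the table swap modeled as instantaneous at the interim week. Absent early
success the trial enrolls to 400 and applies the success rule once more
after the last enrollee's 12-week visit, on complete data with no
imputation. Reported duration is the stopping interim's week for early
stops, otherwise last enrollment week + 12.

The default null scenario — all arms at week-4 rates (quit 0.30,
efficacious 0.25, not efficacious 0.45) with transitions at the elicited
conditional prior means, t_eff = (0.1, 0.7, 0.2) and t_noeff =
(0.1, 0.2, 0.7) — is a package assumption chosen as a clinically
plausible neutral profile; the design's original simulation scenarios
were never published. Under it the measured Type I error is ~5–7 %
(500-trial batches; Monte-Carlo SE ≈ 1 pp), consistent with the design's
nominal ≈ 5 %.

What the simulator does not model: site effects, consent refusal,
dropout other than drug quit, staggered site activation, data-entry lag
(beyond the instantaneous-swap assumption), and accrual variability
(a Poisson accrual mode was considered and left out: with interims
anchored on the enrollment count and quarterly cadence, spacing noise
changes only calendar durations, not allocation behavior). Passing
simulation tests therefore validate the design machinery, not the
behavior of any real multi-site data flow.

## Numerical choices

- Simplex tolerance for utility inputs: |Σθ − 1| ≤ 1e-9.
- All randomness flows through `numpy.random.Generator`; every public
  entry point accepts a seed or generator, child seeds are drawn below
  2^31, and identical seeds reproduce byte-identical outputs (tables,
  reports, manifests). Manifests deliberately carry no wall-clock field —
  provenance is config hash + input digests + seeds — while the
  append-only audit log carries timestamps.
- Monte-Carlo scale defaults (n_draws = 10,000, m = 20) hold the
  MC standard error of P^max near 0.3 pp at the success boundary;
  operating-characteristics runs use 500 trials per scenario, putting
  ≈ 1 pp of standard error on a 5 % rate.
- The test oracles are independent of the engine: Dirichlet moment
  algebra in closed form, and a midpoint-cell quadrature of the utility
  distribution on the probability simplex (grid error ≲ 1e-4 at n = 600,
  valid for concentrations ≥ 1).

## Known limitations

- The information-measure allocation is deliberately exploratory: the
  √ damping and the 1/(n_a+1) factor cap the best arm's allocation share
  near 0.5 per block, and scenarios separated enough to push it higher
  stop early instead, so the equal burn-in keeps the best arm's overall
  enrollment share near 0.35–0.40 across effect sizes. Designs wanting a
  majority of patients on the winning arm need a smaller burn-in, a more
  aggressive allocation rule, or a stricter success threshold.
- V(U_a) pools draws across imputations (including between-imputation
  variance); a single-completion variant would report slightly smaller
  variances.
- The loser rule is evaluated before the success rule at each interim;
  both use the same Monte-Carlo summary, so their errors are correlated.
- The CSV reader treats a filled pain score without a quit flag as
  unobserved (with a warning) rather than guessing the flag.
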