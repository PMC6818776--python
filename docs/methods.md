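# Methods

## Data model

An interaction is coded in contiguous fixed-length intervals (default 2 s;
the length is metadata only — every statistic is index-based). Each dyad is
a binary matrix of T intervals × K behavior categories; co-occurrence
within an interval is legal. The default scheme is the MCAM with seven
main categories — M+, M−, C+, C−, MAlone, CAlone, Together — where the
four attachment categories are aggregated from 16 coded subcategories by
logical OR (a category is present iff at least one of its subcategories
is). Custom schemes are a two-column CSV `subcategory,category`. Interval
indices must form 1..T without gaps; missing intervals are an error, not
imputed, because silent imputation would bias the lag counts. Intervals in
which nothing codable happened must be explicit all-zero rows.

## Sequencing likelihood

For an ordered pair (first, second), the lag-1 contingency over the T−1
interval pairs (t, t+1) gives n11, n10, n01, n00. Then

    Jac_Obs  = n11 / (n11 + n10 + n01)
    Jac_Exp  = p1·p2 / (1 − (1−p1)(1−p2))
    Jac_Norm = (Jac_Obs − Jac_Exp) / (1 − Jac_Exp)

**Window convention.** p1 is the frequency of the first behavior over
intervals 1..T−1 and p2 that of the second over 2..T. With this choice the
observed and expected counts range over identical pair sets, and the
constant-first-behavior configuration yields exactly 0 — the statistic's
null anchor. Full-series frequencies are available via `p_window="full"`
for sensitivity analysis. Profile-level relative frequencies (the
"how often" measures) always use all T intervals: frequency is a property
of the whole interaction, not of a lagged window.

**Undefined values.** Jac_Obs is undefined when n11+n10+n01 = 0; Jac_Exp
when p1 = p2 = 0; Jac_Norm additionally when either behavior never occurs
in its window (the chance correction is then meaningless — a behavior that
is absent cannot be "sequenced at chance level") or when Jac_Exp = 1
(both behaviors constantly present; zero denominator). Undefined values
propagate as missing: they are never reported as 0 and never raise.

**Lag.** Fixed at one interval. Higher-order sequencing is out of scope.
No smoothing or continuity correction is applied to the counts.

## Sample aggregation

For each of the K² ordered pairs the sample summary reports:

- *Dyads*: the number of dyads in which the sequence actually occurs
  (n11 > 0);
- *n_defined*: dyads with a defined Jac_Norm — the denominator for
  everything below. Using all dyads instead would be inconsistent (a
  proportion of 0.61 over 54 dyads cannot be reconciled with only 18 dyads
  showing the behavior at all);
- mean, SD, min, max and the proportion of dyads above chance
  (Jac_Norm > 0), over defined values only;
- an upper-tailed one-sample t-test of the mean against 0 (df = n−1),
  emitted only when n_defined ≥ 2 with nonzero spread.

Frequencies are summarized the same way (they are always defined; no mean
test is attached since they are bounded positive rather than
chance-centered).

## Covariate correlations

Dyad-level covariates are trust (1–4), avoidance and anxiety (1–7).
Associations with every frequency and sequencing measure use Spearman rank
correlations (average ranks for ties), two-sided p. Avoidance and anxiety
overlap; each is therefore also partialled for the other: all three
variables are rank-transformed and the first-order partial correlation
r_xy·z = (r_xy − r_xz·r_yz)/√((1−r_xz²)(1−r_yz²)) is computed on the
ranks, with p from the t approximation at n−3 df. A pairwise coefficient
within floating-point error of ±1 is treated as degenerate. Measures with
fewer than 3 complete pairs or no rank variance are skipped with a
warning. No multiple-testing correction is applied across the measure ×
covariate grid by default (the analysis is exploratory); callers can apply
one to the exported p-values if desired.

## Outlier screening and single-dyad comparison

Sample analyses can exclude extreme dyads on a chosen covariate via
leave-one-out z-scores (sample SD, n−1), default threshold |z| ≥ 3. When
the remaining dyads are constant, a differing held-out value counts as
infinitely extreme and an equal one as z = 0; this keeps the screening
well-defined in the textbook case of one gross outlier in an otherwise
homogeneous sample, while the underlying `zscore_vs_sample` primitive
still raises on a zero-SD reference as its contract states. An excluded
(or any other) dyad can be profiled against the remaining sample with
per-measure z-scores; measures undefined for the target or with a
degenerate reference are reported blank with a note.

## Inter-rater reliability

Cohen's kappa is pooled over all interval × category binary decisions of
two coders: one 2×2 agreement table, chance agreement from the coders'
marginal presence rates. The 95% CI uses the large-sample standard error
√(p_o(1−p_o)/(n(1−p_e)²)); a nonparametric bootstrap over decisions is
available as an option. Because the focal measures are derived quantities,
the per-dyad frequencies and sequencing likelihoods of the two coders are
additionally correlated across all paired defined values (Pearson by
default — the measures are continuous and approximately linearly related
between coders; Spearman is switchable).

## Synthetic dyads

The generator emulates a mother–child sample, not any particular dataset:

- **Streams.** Interval 1 is Bernoulli at each category's base rate.
  Afterwards an uncoupled category stays Bernoulli(base rate); a coupled
  pair (first, second, q1, q0) draws the second category at t+1 from
  Bernoulli(q1) if the first was present at t, else Bernoulli(q0). This
  first-order Markov coupling is the minimal mechanism producing nonzero
  Jac_Norm. When several couplings target one category the conditionals
  combine by noisy-OR, which keeps probabilities valid without
  renormalization.
- **Defaults.** 54 dyads, T = 90 (≈3 min of 2-s intervals), the seven
  MCAM categories at the published sample's mean rates (M+ .45, M− .02,
  C+ .39, C− .05, MAlone .13, CAlone .47, Together .04), couplings on the
  pairs that dominate such samples (strong auto-loops of the task
  categories and of M+/C+, cross-lags M+↔C+ and M−→C−). Coupling
  conditionals are parameterized marginal-preservingly
  (q0 = p₂ − p₁·gap, q1 = q0 + gap) so the second stream's base rate is
  unchanged; for multi-source targets each conditional is tempered with a
  1/m exponent so the noisy-OR combination still reproduces the base rate
  (default-world mean frequencies land within ~0.03 of the configured
  rates for the frequent categories, slightly high for the rare ones).
- **Heterogeneity and covariates.** Each dyad's (q1, q0) are drawn around
  the configured values (SD 0.05). Covariate scores are
  mean + sd·(r·signal + √(1−r²)·noise), where the signal is the
  weight-combined standardized deviation of the dyad's realized coupling
  gaps, r = 0.6 by default, and the result is truncated to the instrument
  range. Default moments (trust 3.51 ± 0.32, avoidance 2.44 ± 0.84,
  anxiety 2.11 ± 0.79) emulate the published questionnaire sample; default
  links: trust negatively to the negative-behavior couplings (M−→C−,
  C−→C−), avoidance positively to the M+ auto-loop and M−→C−, anxiety
  positively to M−→C−. These are emulation targets, not claims.
- **Reproducibility.** Per-dyad substreams are derived deterministically
  from (seed, dyad_index); covariate noise uses a separate tagged
  substream. Identical configs produce bit-identical samples.
- **What a green test does not establish.** The generator produces
  stationary, conditionally independent streams with Gaussian covariate
  noise. Real coded interactions are non-stationary (stress decays over
  the reunion), have coder autocorrelation, structural exclusions between
  categories (e.g. MAlone and Together rarely co-occur by definition), and
  covariates measured with instrument error. Passing tests demonstrate
  that the estimators recover the stated generative structure, not that
  the model captures real dyadic dynamics.

## Networks

The sample network encodes: node size = mean relative frequency, floored
at a minimum size (default 0.05) for label readability; a directed edge
for every pair whose mean sequencing likelihood is significant at alpha,
weighted by |mean|, solid for positive (more often than chance) and dashed
for negative; auto-loops downscaled by 0.5 by default. Because the mean
test is upper-tailed, a negative mean is drawn when its lower-tail
evidence 1 − p is below alpha. Correlation networks use |rho| for node
size and edge weight, grey/black shading for positive/negative, and only
significant links. Size/width scaling constants are configurable linear
mappings (only the floor and the downscaling are principled; any monotone
mapping is acceptable). Exports are deterministic DOT (visual attributes
resolved: penwidth and greyscale saturation linear in |weight|, clipped at
a configurable maximum) and GraphML (raw attributes; round-trips to an
attribute-equal spec). Layout is delegated to the consumer; the circular
category order is emitted as a `node_order` hint.

## Numerical and design choices

- Undefined statistics are encoded as `None`/empty CSV cells, never NaN
  sentinels inside the algebra.
- The t-test, Spearman and rank transforms are delegated to scipy; the
  contingency counting, Jaccard algebra, partial-correlation formula,
  pooled kappa and the generator are implemented here and cross-checked in
  the test suite against independent oracles (enumeration loops,
  hand-formula implementations, sklearn's kappa, pingouin's partial
  correlations).
- Zero-variance inputs raise informative errors at the primitive level;
  table-level drivers skip and log instead of failing the run.
- Exit codes of the CLI: 0 success, 1 input error, 2 configuration error.
- All conventions of a run (p-window, denominators, alpha, thresholds,
  exclusions, seed) are written to `run_log.json`, so outputs are
  self-describing; repeated runs are byte-identical.

## Known limitations

- Inference treats dyads as independent units; no actor–partner or
  mixed-effects modeling of interdependence.
- The t-test on mean Jac_Norm ignores the varying per-dyad precision of
  the statistic (short series and rare behaviors give noisy values).
- Binary codes only; ordinal intensity codes are out of scope.
- The pooled-kappa SE treats pooled decisions as independent, which
  interval autocorrelation violates; the bootstrap option resamples
  decisions, not intervals, and shares the limitation.
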