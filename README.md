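# dyadseq

Lag-sequential analysis of micro-coded dyadic interaction.

`dyadseq` is for researchers who code an interaction between two partners
(prototypically a mother–child dyad in a stressful problem-solving task) in
short fixed intervals, registering for each interval the presence (1) or
absence (0) of a set of behavior categories. From such interval-coded data
the package quantifies, per dyad, **how often** each behavior occurs and
**how likely** one behavior is to follow another in the next interval, and
then aggregates and tests these measures across a sample.

## The statistic

For an ordered behavior pair *(first, second)*, count over the T−1 lag-1
interval pairs (t, t+1):

- n₁₁ — first present at t and second present at t+1,
- n₁₀ — first present at t, second absent at t+1,
- n₀₁ — second present at t+1 without the first at t.

The observed Jaccard association and its chance expectation given the
behaviors' relative frequencies p₁, p₂ are

```
Jac_Obs = n11 / (n11 + n10 + n01)
Jac_Exp = p1 · p2 / (1 − (1 − p1)(1 − p2))
```

and the chance-corrected **sequencing likelihood** is

```
Jac_Norm = (Jac_Obs − Jac_Exp) / (1 − Jac_Exp)
```

Jac_Norm = 0 means the sequence occurs exactly as often as expected by
chance; 1 means the two behaviors always follow each other; negative values
mean the sequence is avoided. By default p₁ is taken over intervals 1..T−1
and p₂ over 2..T (lag-aligned windows), so observed and expected counts
range over the same pair set. Pairs may be auto-loops (first = second),
which measure behavioral persistence.

On top of the per-dyad profiles the package provides: upper-tailed
one-sample t-tests of the mean sequencing likelihood, proportions of dyads
above chance, Spearman and partial Spearman correlations with dyad-level
covariates (trust, avoidance, anxiety), pooled Cohen's kappa and
coder-measure correlations for inter-rater reliability, z-score comparison
of a single dyad against the sample, directed-network views of the average
dynamics and of covariate correlations (DOT/GraphML), and a seeded
generator of coupled binary behavior streams with covariates linked to the
coupling strength.

## Worked example

Sequencing of positive mother behavior (M+) followed by positive child
behavior (C+) in a toy 5-interval dyad:

```python
import pandas as pd
import dyadseq as dq

series = dq.BehaviorSeries("d01", pd.DataFrame({"M+": [1, 0, 1, 1, 0],
                                                "C+": [0, 1, 1, 0, 1]}))
stat = dq.jaccard_normalized(series, "M+", "C+")
print(stat.contingency)                        # LagContingency(n11=2, n10=1, n01=1, n00=0)
print(stat.p1, stat.p2)                        # 0.75 0.75
print(stat.jac_obs, stat.jac_exp, stat.jac_norm)  # 0.5 0.6 -0.25
```

Two of the four lag-1 pairs show C+ following M+ (Jac_Obs = 0.5), but with
both behaviors present 75% of the time chance alone predicts Jac_Exp = 0.6,
so the sequence occurs *less* than expected: Jac_Norm = −0.25.

A full sample run on synthetic data (54 dyads, 90 two-second intervals,
seven categories with persistent and cross-lagged couplings):

```python
bundle = dq.run_analyze(dq.RunConfig(generator=dq.default_config(seed=7),
                                     out_dir="out"))
print(dq.inference.summaries_to_frame(bundle.seq_summaries)
        .sort_values("mean", ascending=False).head(3).to_string(index=False))
```

```
         measure  dyads  n_defined  prop_positive     mean       sd      p_value
CAlone => CAlone     54         54       1.000000 0.371797 0.114470 2.516204e-30
MAlone => MAlone     50         52       0.923077 0.185432 0.123558 4.071935e-15
        M- => C-     16         26       0.615385 0.126561 0.223512 3.951613e-03
```

Each row summarizes one ordered pair across the sample: `dyads` counts
dyads in which the sequence actually occurs (n₁₁ > 0), `n_defined` those
for which the statistic is defined, `prop_positive` the share of defined
dyads above chance, and `mean`/`p_value` the average likelihood with its
upper-tailed t-test. The run directory additionally contains the per-dyad
profiles, frequency summaries, covariate correlation tables, network
exports (`network_sample.dot`, per-covariate correlation networks) and a
`run_log.json` recording every convention used.

The same pipeline is available from the shell:

```
dyadseq simulate --out data --n-dyads 54 --intervals 90 --seed 7
dyadseq analyze --input data/behavior.csv --scores data/scores.csv --out out
dyadseq compare-dyad --input data/behavior.csv --dyad d007 --out out
```

## Acceptance script

`scripts/acceptance.py` recomputes the package's analytic anchor from
scratch: it builds the perfect-following two-stream series (the second
behavior at t+1 exactly when the first occurred at t), runs the lag-1
contingency and normalized-Jaccard computation through the package, and
writes the resulting value as JSON:

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Documentation

See `docs/methods.md` for the model, conventions (windows, undefined
statistics, aggregation denominators), the synthetic-data generator's
design and limits, and numerical choices.
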