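# touchdid

Causal surveillance of **touch desire** and **touch avoidance** in a tweet
stream: did an infectious-disease outbreak change how often — and about
what — people post that they *want to touch* or *don't want to touch*
something?

The package is aimed at infodemiology / behavioural-epidemiology analysts.
It implements the full analysis chain around a rolling difference-in-
differences (DID) design, and ships a seeded synthetic tweet-stream
generator so every stage is testable end to end without any platform data
(raw tweet corpora are generally not redistributable).

## The method

**Data model.** Posts matching touch-desire / touch-avoidance queries are
cleaned by an exclusion cascade (exact-duplicate bot posts removed keeping
the earliest copy; URL posts dropped; "noisy" targets blocklisted), and
each surviving post carries a *target word* classified by a six-category
lexicon (body part, animal, object, person, geometry, temperature) that
collapses to an animate/inanimate dichotomy.

**Tweet proportion.** Raw counts confound behaviour with platform growth,
so the monthly outcome is a proportion `Y = (attitude posts) / (pseudo-
baseline)`, where the pseudo-baseline counts posts bearing a ubiquitous
marker token inside one uniformly placed 30-second window per 3-hour block
(expectation 30/10800 of all marker posts). Aggregating every third day
gives three proportion samples per month.

**Design.** Seven 18-month groups, each running August of its first year
through January of its third year: the window spanning the outbreak
(August 2019 - January 2021) is the treatment group, the six windows
starting 2013-2018 are controls. Months 1-6 are pre-treatment; the post
period splits into three infection waves (Feb-Jun, Jul-Nov, Dec-Jan).
With month index m, event time is k = m - 7 (reference k = -1).

**Models.** Proportions are positive with roughly constant coefficient of
variation, so all models are Gamma GLMs with the inverse (canonical) link,
fitted by IRLS:

    1/Y_gm = alpha (Treat_g x Post_m) + gamma Post_m + mu_g            (overall)
    1/Y_gm = sum_w alpha_w (Treat_g x Wave_wm) + gamma_w Wave_wm + mu_g  (waves)
    1/Y_gm = sum_{k != -1} alpha_k (Treat_g x Month_mk) + lambda_m + mu_g (event study)

`mu_g` are control-group fixed effects (the treatment group sits in the
intercept) and the common period terms carry the control groups'
post-vs-pre contrast, so `alpha` is the double difference that cancels
shared seasonality and long-term trend. Because the link is `1/mu`,
coefficient signs are reversed relative to the response; every effect is
therefore also reported as an average response-scale effect (absolute and
relative) with confidence limits mapped through the link. Pre-period
event-study contrasts (k < 0) diagnose the parallel-trends assumption.

**Quality analysis.** Which targets are mentioned is tracked by (i) the
cosine similarity of each month's target-word probability distribution to
the group's own pre-treatment template, re-analysed with the same DID
machinery, and (ii) a bootstrap test of per-word probability shifts
between treatment and pooled control periods: multinomial resampling
(B = 10,000) with one-tailed Bonferroni-corrected 95% bounds over the
top-15/bottom-15 selected words.

## Worked example

Simulate a panel with a +30% multiplicative post-outbreak effect on the
attitude rate, and estimate it:

```python
import touchdid as td
from touchdid.studies import calibration_config

panel = td.generate_panel(calibration_config(7, effect_overall=1.3),
                          independent_cells=True)
data = td.subset_dataset(panel, "desire", "animate")
est = td.DIDEstimator(model="overall").fit(data)
print(est.effects_[["term", "coef", "se", "p_value",
                    "effect_rel", "effect_rel_lo", "effect_rel_hi",
                    "significant"]].round(4).to_string(index=False))
```

```
      term    coef     se  p_value  effect_rel  effect_rel_lo  effect_rel_hi  significant
treat_post -0.0582 0.0172   0.0007      0.2725         0.0992         0.5107         True
```

The linear-predictor coefficient is *negative* (the inverse link moves
`1/Y` down when `Y` goes up) while the response-scale relative effect,
+27.3% with 95% CI [9.9%, 51.1%], recovers the injected +30%. The
event-study curve from the same panel shows no significant pre-outbreak
contrast (parallel trends) and diverges from k = 0:

```python
curve = td.EventStudyEstimator().fit(data).curve_
print(curve[["k", "coef", "ci_lo", "ci_hi", "significant"]].round(4).head(9).to_string(index=False))
```

```
 k    coef   ci_lo   ci_hi  significant
-6  0.0706 -0.0348  0.1760        False
-5 -0.0079 -0.1012  0.0853        False
-4  0.0140 -0.0806  0.1086        False
-3  0.0108 -0.0874  0.1091        False
-2  0.0670 -0.0404  0.1743        False
-1  0.0000  0.0000  0.0000        False
 0 -0.1003 -0.1837 -0.0170         True
 1 -0.0377 -0.1255  0.0502        False
 2  0.0266 -0.0698  0.1229        False
```

The whole chain is also available from the shell:

```sh
touchdid run-all --seed 1 --out results/
touchdid simulate --seed 1 --out stream.jsonl
touchdid filter --stream stream.jsonl --out classified.csv
touchdid did --panel panel.csv --attitude desire --animacy animate --model waves --out did.csv
```

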