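# selfexcite

Detecting contagion in event time series recorded at day resolution.

Many kinds of adverse events — disease cases, violent incidents, suicides —
are suspected of being *self-exciting*: each event temporarily raises the
probability of another one in the following days.  When the effect is
subtle, analyses that coarsely bin the inter-event times (e.g. "what
fraction of events fall within two weeks of the previous one?") or that
compare only the mean and variance of the gap distribution can fail to
reject a no-contagion null even when the data carry enough information to
do so.  `selfexcite` is a toolkit for researchers in epidemiology and the
social sciences who want the sensitive alternative: an **unbinned
likelihood fit of a Hawkes-type self-excitation model on daily counts**,
together with Monte Carlo machinery that quantifies, by simulation, how
much statistical power the coarse methods give up.

## The model

Event dates are binned into a daily count vector $N^{obs}_i$ over an
$M$-day study span (day binning is forced by the data: time of day is
rarely recorded).  An event on day $t_i$ raises the probability of an
event on a later day $t_j$ by an exponential kernel integrated over the 24
hours of that day,

$$P(t_j \mid t_i, T_{excite}) = e^{-(t_j-t_i-1)/T_{excite}} - e^{-(t_j-t_i)/T_{excite}},$$

which telescopes to total mass 1 over all future days.  The conditional
expected count on day $t_n$ is

$$N^{exp}(t_n) = N_0(t_n) + N_{secondary} \sum_{t_i < t_n} P(t_n \mid t_i, T_{excite}),$$

where the sum runs over all prior events, $N_{secondary}$ is the branching
ratio (mean secondary events incited per event; subcritical when $< 1$)
and $N_0(t)$ is a baseline rate — a constant, or a running mean of the
data, optionally modulated by day-of-week weights.  The two contagion
parameters are estimated by minimising the Poisson negative log-likelihood
over **every day of the span, zero-count days included**,

$$-\log L = \sum_{i=1}^{M}\left[N^{exp}(t_i) - N^{obs}_i \log N^{exp}(t_i)\right],$$

subject to the constraint $\sum_i N^{exp}(t_i) = \sum_i N^{obs}_i$, which
fixes the baseline normalisation.  A Negative Binomial (NB2) likelihood is
available for over-dispersed data.  The contagion model is compared with
the baseline-only null via the Wilks likelihood ratio test and AIC, and
95% confidence intervals come from the profile likelihood.

The package also implements, deliberately, the coarse methods it argues
against — the two-bin within-14-days proportion test, one-sample t and
variance-ratio moment tests — plus forward simulators for both hypotheses,
so their type-I error and power can be measured head to head.

## Worked example

Simulate an eight-year series under contagion (branching ratio 0.28,
13-day decay, calibrated to 232 expected events — the scale of the
2006–2013 U.S. mass-killing record), then fit it:

```bash
$ selfexcite simulate --model contagion --events 232 --span-days 2922 \
    --reps 1000 --seed 7 --out-dir demo --dump-events
average gap mean 12.67 d, variance 219.3, fraction <= 14 d: 0.708

$ selfexcite fit --input demo/events.csv --out demo/fit.json
n_secondary = 0.1919, t_excite = 7.36 d, LRT p = 0.02094
```

The first command reports ensemble gap statistics over 1,000 replicates:
clustering inflates the per-realization gap variance (219 vs ~157 for a
uniform-in-time null at the same rate) while barely moving the mean gap or
the 14-day fraction (0.708 vs ~0.685) — which is exactly why two-bin and
moment summaries struggle to see it.  The second command fits one
realization: the point estimate (0.19, 7.4 d) sits inside sampling noise
of the generating values, the 95% profile CI for the branching ratio is
[0.036, 0.439], and the likelihood-ratio test rejects the no-contagion
null at p = 0.021 on this same dataset.  `demo/fit.json` holds the full
machine-readable report (estimates, CIs, AICs, the resolved
configuration).

The null counterpart

```bash
$ selfexcite simulate --model null --events 232 --span-days 2922 --reps 1000 --seed 7
average gap mean 12.58 d, variance 158.1, fraction <= 14 d: 0.684
```

and `selfexcite power --reps 500 --seed 1` (type-I error and power of each
method at the same study conditions) complete the comparison.
`selfexcite gapstats --input events.csv` applies the coarse tests to a
user-supplied event file.

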