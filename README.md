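# syncphase

Quantifying dyadic body-motion synchrony from triaxial accelerometer
recordings.

When two people talk, their head movements couple: a listener's nods and
backchannel gestures track the speaker's rhythm with a characteristic
lag of tens to hundreds of milliseconds. This temporal coupling —
body-motion synchrony — is a measurable signature of social attunement,
and its disruption is of clinical interest in autism spectrum disorder
(ASD), where listeners synchronize less often and less precisely.
`syncphase` implements a peak-based phase-difference pipeline for
forehead-mounted 100 Hz triaxial accelerometers, the four
distribution-based synchrony features built on it, the between-group
statistics used to compare dyad populations, and a synthetic dyad
simulator with event-level ground truth for end-to-end validation.

## Method

For each participant, the triaxial acceleration is collapsed to its
Euclidean norm

    a(t_i) = sqrt(a_x(t_i)^2 + a_y(t_i)^2 + a_z(t_i)^2),

z-scored over the whole trimmed recording, `a'(t_i) = (a(t_i) − ā)/σ_a`
(sample SD, divisor T−1), which removes individual differences in
movement amplitude, and smoothed with an 11-sample (100 ms at 100 Hz)
forward moving average. A sample is a movement peak if it is a strict
local maximum of the smoothed signal with amplitude ≥ 2.0 (two SDs
above the person's mean movement level).

For a dyad, each speaker peak at `t_i` is paired with the nearest
listener peak `t_j` within ±1.0 s; the signed lag `t_j − t_i` (positive
= listener follows) is a phase difference. Matching is one-to-one: a
listener peak is claimed by at most one speaker peak, conflicts resolved
by ascending absolute offset. The per-dyad lag distribution yields four
features:

| feature | definition | reads as |
|---|---|---|
| density | matched events per minute | synchrony activity |
| mean | mean lag (ms) | directionality (leader–follower) |
| SD | sample SD of lags (ms) | variability (temporal precision) |
| kurtosis | excess kurtosis of lags | coherence (convergence on the typical lag) |

Groups of dyads are compared with Student's pooled-variance t-test
(df = n₁ + n₂ − 2) and Cohen's d standardized by the pooled SD, plus
Mann–Whitney U for ordinal ratings, Pearson correlations for duration
controls, and leave-one-dyad-out sensitivity checks. With equal group
sizes, printed group summaries (mean, SD, n) fully determine t and d, so
published summary tables can be re-analyzed directly.

## Worked example

```bash
python examples/analyze_single_dyad.py
```

simulates a 10-minute TD-like dyad (speaker nodding ~23/min, listener
responding to ~41% of nods at a +90 ms lag) and runs the full pipeline:

```
speaker peaks detected : 229 (true nod events: 229)
listener peaks detected: 123 (true nod events: 123)
matched synchrony events: 116
density    :  11.60 events/min  (synchrony activity)
mean lag   :   55.0 ms          (directionality; + = listener follows)
lag SD     :  320.4 ms          (variability)
kurtosis   :   0.53             (coherence; excess, normal = 0)
central mass within ±300 ms of the mean lag: 65.5%
```

Every true nod is recovered as a peak; about half the speaker's nods
draw a listener response, giving ~11 matched events/min whose lags
cluster (66% within ±300 ms of the mean) around a positive,
listener-follows offset. `examples/reproduce_published_stats.py` runs
the statistical layer on published group summaries, and
`examples/simulate_corpus_and_compare.py` simulates an 18 + 18 dyad
study and recovers the group contrast end to end.

The same pipeline is available as a shell tool:

```bash
syncphase simulate --out corpus/ --seed 1
syncphase analyze --manifest corpus/manifest.yaml --out results/
syncphase compare --features results/features.csv
```

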