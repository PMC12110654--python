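# Methods

## Signal pipeline

The pipeline converts each participant's triaxial trace into a train of
movement-peak times, then converts a dyad's two trains into a
distribution of signed lags.

**Magnitude.** The Euclidean norm of (ax, ay, az) per sample. Axis
information is deliberately discarded: the method targets *when* the
head moves, not how. Sensor units (g or m/s²) are carried but never
converted — the next step makes everything unit-free.

**Normalization.** Z-scoring over the entire trimmed recording, with
the sample SD (divisor T−1). The mean and SD are computed on the active
window only (the recording is defined by its start/end markers, so
"entire recording" means the trimmed window). This removes individual
differences in movement amplitude from head size or speaking style;
consequently the whole pipeline is invariant under affine rescaling of
a trace, a property the test suite asserts end to end.

**Smoothing.** An 11-sample moving average (100 ms at 100 Hz: the 11
samples span 100 ms between first and last). The window is *forward*
(causal): output i averages inputs i..i+10 and keeps input timestamp i,
so the output is shorter by 10 samples and the smoothed signal is
advanced ~50 ms relative to the physical movement. Both members of a
dyad receive the identical shift, which cancels exactly in every
pairwise lag; a `centered=True` option re-anchors the timestamp at the
window midpoint for single-trace timing work. `window_samples`, not
milliseconds, is the canonical parameter.

**Peak detection.** A peak is an interior sample strictly greater than
both neighbors with amplitude ≥ 2.0 (inclusive). Plateaus of exactly
equal samples are not peaks — strictness is the printed rule, and float
plateaus have measure zero on real data. No refractory period is
imposed; the smoothing window provides de facto separation. Endpoints
are never peaks.

**Matching.** Iteration runs over *speaker* peaks (the design isolates
listener responsiveness); each speaker peak takes the nearest listener
peak, and the pair contributes the signed lag listener − speaker (ms)
if |lag| ≤ 1000 ms. Matching is one-to-one by default — a listener peak
is consumed once, conflicts resolved greedily by ascending absolute
offset — so a single listener nod cannot inflate the event count
against several speaker peaks. A `many_to_one` mode reproduces the
permissive reading. Exact ties between a preceding and a following
listener peak break toward positive lag, consistent with backchannel
(listener-follows) semantics. These conventions are explicit package
choices, documented and switchable rather than claimed to be uniquely
correct.

## Features

Per dyad: density = n / duration (duration from the trimmed window, not
the first-to-last peak span); mean lag; sample SD (n−1); excess
kurtosis with standard small-sample bias correction (normal → 0).
The kurtosis convention matters: group means near zero are plausible
for excess kurtosis and implausible for raw (normal → 3), which is why
excess is the default; `raw` and `population` variants are available.
Features with insufficient events are NaN, never 0: one event has a
mean but no SD (n ≥ 2), and kurtosis needs n ≥ 4 and nonzero variance.

## Group statistics

Student's pooled-variance t (df = n₁+n₂−2) with pooled-SD Cohen's d;
the pooled test is identified by the reported df = 34 at 18 + 18 dyads.
Welch's test is available behind a flag; d stays pooled-SD either way.
Two-sided p throughout. Mann–Whitney U uses midrank ties, exact
enumeration when both n ≤ 8 and no ties are present, otherwise the
tie-corrected normal approximation (continuity correction on by
default, switchable). Pearson r takes its two-sided p from the t
transform with df = n−2. No multiple-testing correction is applied by
default; a Holm step-down helper exists. `t_and_d` accepts raw samples
or (mean, SD, n) summaries and guarantees the two paths agree to
machine precision — with equal n, printed summaries fully determine
both statistics.

## Missing data

Recordings are laid on the uniform grid implied by the nominal rate.
Gaps (absent grid samples or NaN) of ≤ 3 samples (30 ms, below the
smoothing window) are linearly interpolated and do not count as
missing; longer gaps count toward the missing fraction, and a session
whose fraction exceeds 5% is rejected with the fraction attached.
Passing sessions have their long gaps filled too, so downstream code
always sees a complete grid. Time columns are accepted in seconds or
milliseconds (auto-detected by magnitude, overridable). Windowing is
half-open [start, end), making adjacent segment durations additive.

## The synthetic dyad generator

The generator is event-based: the analysis detects discrete peaks, so
ground truth must be discrete events to permit exact recall/precision
accounting (a coupled-oscillator model would have no event-level truth
to score against).

**Event layer.** Speaker nods form a dead-time renewal process: gaps
are 2·nod_width plus an exponential whose rate is chosen so the
*realized* mean rate equals `speaker_nod_rate_per_min` (naive thinning
of a Poisson stream would undershoot the configured rate by ~25% at
defaults). Each nod draws a listener response with probability
`response_prob`, at a lag ~ Normal(lag_mean, lag_sd) truncated to ±1 s
so every coupled pair stays inside the matching window and recovery
targets are exact. Spontaneous listener nods arrive as an independent
Poisson process; listener events closer than one nod width are merged
with coupled responses winning. Configs that violate the separation
constraint raise errors.

**Rendering.** Each event is a raised-cosine pulse (default width
400 ms — one pulse yields exactly one smoothed peak) on the vertical
axis with 20% leakage onto a horizontal axis, on top of a 1 g gravity
offset, background body motion, and white Gaussian sensor noise
(`noise_sd` = 0.01 g, typical MEMS noise at 100 Hz).

Background motion deserves explanation. In real recordings the
non-event variance is dominated by continuous body motion — breathing,
postural sway, speech-related movement — not by sensor noise. This
matters after z-normalization: *something* must carry the baseline
variance, and if white noise does, its normalized amplitude is large
enough to split smoothed pulse tops into duplicate peaks. The generator
therefore renders background as bounded two-tone quasi-periodic sway
(a breathing component at 0.18–0.35 Hz plus a postural component at
0.7–1.1 Hz, amplitude ratio 0.45, random frequencies and phases per
trace, RMS `background_rms` = 0.1 g). The amplitude ratio bounds the
normalized sway peak at (1+r)/sqrt((1+r²)/2) ≈ 1.87 < 2.0, so
background alone can never trigger the detector — even on a trace with
no nod events at all, where normalization inflates sway to unit
variance. This makes the zero-coupling contract exact (no responses, no
spontaneous nods ⇒ zero detected listener peaks ⇒ zero matches), which
no Gaussian-tailed background could achieve.

**Amplitude calibration.** `nod_amplitude_z` (default 3.5) specifies
the pulse height *after* normalization, but the normalization statistics
depend on the rendered signal itself. With pulse duty cycle p, pulse
mean 1/2 and mean square 3/8 over its support, the signal mean is pA/2
and its variance A²(3p/8 − p²/4) + background² + noise²; setting
(κA − pA/2)/SD = z (κ = moving-average attenuation of the pulse peak)
solves for the raw amplitude A in closed form. The target saturates
when pulse variance dominates (z ≈ 3.8 at the default speaker rate and
width); unreachable targets raise an error. Calibration uses the
*expected* event count from the configured rate, keeping feasibility a
deterministic property of the config, and one amplitude per dyad is
calibrated from the speaker side — nod vigor is a property of the
person, so the listener, who moves less overall, shows larger
normalized peaks, as real quiet listeners do.

**Regimes.** The TD-like preset (rate 23.3/min, response_prob 0.41, lag
90 ± 300 ms, 2 spontaneous nods/min) emerges from the pipeline with
density ≈ 9.6–10.5 events/min, per-dyad lag SD ≈ 310 ms and ±300 ms
central mass ≈ 66%. The ASD-like preset (response_prob 0.18, lag SD
450 ms, 4 spontaneous nods/min) yields density ≈ 6/min, lag SD ≈
430 ms and negative excess kurtosis; response_prob is set below the
naive density ratio because chance matches of spontaneous nods add
~1.7 events/min to the matched set. Note that spontaneous listener
motion contaminates matched lags with zero-centered, quasi-uniform
chance pairs; parameter-recovery checks therefore run with the
spontaneous rate at zero, and the recovered lag mean in coupled-only
configs still sits ~4–5 ms low because detection timing jitter
interacts with nearest-peak selection.

**What the generator does not emulate.** Biomechanically realistic nod
kinematics (real nods are biphasic, variable in width and amplitude),
speaker–listener entrainment drift over the session, amplitude
heterogeneity between dyads, non-stationary nod rates, and heavy-tailed
lag distributions. In particular the truncated-normal + uniform lag
mixture is platykurtic: simulated per-dyad excess kurtosis runs ~0.2
(TD-like) to −0.5 (ASD-like), below the values real dyads show, so
passing tests demonstrate correct *recovery of injected parameters* and
correct *direction and separability of regime contrasts*, not that real
data look like the simulator.

## Problem sizes and numerical choices

Tests and the acceptance script size simulations for single-CPU runs:
parameter recovery uses one 30-minute dyad (~280 matched events); the
power check uses 20 replicate corpora of 18 + 18 dyads at 5 minutes per
session; the acceptance corpus uses 10-minute sessions. Statistical
reproductions from printed summaries are compared at one unit in the
last printed decimal (the summaries themselves are rounded). Histogram
bins are left-closed with the final bin closed, so a lag of exactly
+1000 ms is counted. Exact matching ties break toward positive lag.
Degenerate inputs fail loudly: constant signals (zero variance), empty
trim windows, histograms on empty sets (flagged, not fabricated), and
kurtosis below n = 4 all surface as typed errors or NaN rather than
silent zeros.

## Known limitations

The matching convention (speaker-anchored, one-to-one, greedy) is one
defensible reading of nearest-peak pairing; alternatives are exposed as
options, and results at high peak densities depend on the choice.
Peak-based lags quantify event alignment only — no windowed
cross-correlation, surrogate-pair baselines, or time-varying synchrony.
The statistical layer assumes independent dyads and (for the pooled
test) equal variances; Welch and nonparametric options exist but
mixed-model or Bayesian treatments are out of scope.
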