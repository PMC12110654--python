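"""Between-group statistics from printed summary values.

With equal group sizes, the pooled two-sample t and pooled-SD Cohen's d
are fully determined by each group's mean, SD and n — so published
summary tables can be re-analyzed without raw data.  The summaries below
are the TD (first) and ASD (second) group values of a dyadic head-motion
synchrony study; ``t_and_d`` accepts them directly.
"""

import syncphase as sp
from syncphase.group_stats import Summary

comparisons = {
    "density (events/min)": (Summary(9.63, 3.23, 18), Summary(5.96, 2.73, 18)),
    "mean lag (ms)":        (Summary(90.0, 61.6, 18), Summary(84.4, 187.2, 18)),
    "lag SD (ms)":          (Summary(311.1, 51.8, 18), Summary(384.4, 86.1, 18)),
    "kurtosis (excess)":    (Summary(0.81, 0.84, 18), Summary(0.13, 1.01, 18)),
}

print(f"{'feature':<22}{'t(34)':>8}{'p':>10}{'d':>7}")
for name, (td, asd) in comparisons.items():
    r = sp.t_and_d(td, asd)
    print(f"{name:<22}{r.t_stat:>8.2f}{r.p_two_sided:>10.4f}{r.cohens_d:>7.2f}")

aq = [30, 28, 30, 21, 38, 33, 35, 34, 38, 36, 35, 30, 10, 32, 22, 37, 38, 23]
mean, sd = sp.aq_summary(aq)
print(f"\nASD-group AQ: mean {mean:.2f}, SD {sd:.2f} (n = {len(aq)})")
print("\nLarge effects on density, lag SD and kurtosis; no effect on the")
print("mean lag: group differences lie in how *often* and how *tightly*")
print("listeners synchronize, not in the direction of the lag.")
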