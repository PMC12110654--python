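"""Two-group synthetic study: TD-like vs ASD-like dyads.

Simulates 18 dyads per regime (the ASD-like listener responds less
often, with broader lags and more uncoupled movement), analyzes every
session, and runs the between-group statistics on the four features.
"""

import syncphase as sp
from syncphase.pipeline import analyze_records

records = sp.simulate_group_study(
    sp.td_like_config(duration_s=600.0),
    sp.asd_like_config(duration_s=600.0),
    n_dyads_per_group=18,
    seed=11,
)
features, _ = analyze_records(records)

print(features.groupby("group")[
    ["density_per_min", "mean_ms", "sd_ms", "kurtosis_excess"]
].mean().round(2))
print()

report = {}
for metric in ["density_per_min", "mean_ms", "sd_ms", "kurtosis_excess"]:
    report[metric] = sp.compare_groups(features, [metric])[metric]

print(f"{'metric':<18}{'t':>8}{'df':>5}{'p':>10}{'d':>7}")
for metric, r in report.items():
    print(f"{metric:<18}{r.t_stat:>8.2f}{r.df:>5.0f}{r.p_two_sided:>10.2g}"
          f"{r.cohens_d:>7.2f}")
print("\nPositive t/d: first group (TD-like) larger. The density, lag-SD")
print("and kurtosis contrasts mirror the group differences the method is")
print("designed to expose. The mean lag also drops in the ASD-like")
print("regime here because uncoupled listener movement dilutes the")
print("matched set with zero-centered chance lags.")
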