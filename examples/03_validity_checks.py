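"""Agreement between model-based C/IER posteriors and heuristic indicators.

Computes fixed 2-s / 1-s per-item thresholds and the 30% normative
threshold on simulated sessions, their point-biserial agreement with the
mixture posteriors, the weighted correlation of posteriors with omission
counts, and the lagged rank-order consistency of posteriors across scales.
"""

import numpy as np

import screenweight as sw
from screenweight.simulate import SimulationConfig, simulate_dataset

ds = simulate_dataset(SimulationConfig(n_groups=1, n_per_group=1200,
                                       n_scales=6, cier_proportion=0.08,
                                       seed=56))
weights, _ = sw.decompose_screen_times(ds.screen_records, seed=56)
report = sw.validity.validity_report(weights, ds.screen_records,
                                     ds.responses)

per_stat = report.groupby("statistic")["value"].mean()
print("mean over scales:")
for stat in ("flag_rate_2s", "flag_rate_1s", "flag_rate_nt30"):
    print(f"  {stat:18s} {per_stat[stat]:.3f}   "
          f"(point-biserial with posterior: "
          f"{per_stat[stat.replace('flag_rate', 'pbis_posterior')]:.2f})")
print(f"  posterior-omission correlation: "
      f"{per_stat['cor_posterior_omissions']:.2f}")

piv = weights.pivot_table(index="respondent_id", columns="scale_id",
                          values="posterior_cier")
lags = sw.lagged_consistency(piv.to_numpy(), max_lag=5)
print("lagged consistency of posteriors (mean r by scale-position lag):")
print("  " + ", ".join(f"lag {int(r.lag)}: {r.mean_correlation:.2f}"
                       for r in lags.itertuples() if r.n_pairs))
print("-> thresholds flag only parts of the identified C/IER while "
      "omissions and posteriors coincide strongly; lagged correlations sit "
      "near zero here because this generator draws carelessness "
      "independently on every screen.")
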