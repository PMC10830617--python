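"""Attentiveness-weighted multi-group GPCM versus the unadjusted fit.

Simulates two groups whose latent means differ by 1.0, contaminates 20% of
respondents with careless response patterns, and compares the group-mean
estimates from the unadjusted pseudo-likelihood fit with those from the fit
that multiplies sampling weights by attentiveness weights (here: near-zero
for the contaminated cases).
"""

import numpy as np

import screenweight as sw
from screenweight.simulate import SimulationConfig, simulate_dataset

cfg = SimulationConfig(n_groups=2, n_per_group=1200, n_scales=1,
                       cier_proportion=0.20, group_means=(0.0, 1.0),
                       group_sds=(1.0, 1.2), seed=34)
ds = simulate_dataset(cfg)
weights, _ = sw.decompose_screen_times(ds.screen_records, seed=34)

sid = next(iter(ds.responses))
resp = ds.responses[sid].merge(
    weights[["respondent_id", "attentiveness_weight"]], on="respondent_id")
rec = ds.screen_records[["respondent_id", "sampling_weight"]]
resp = resp.merge(rec, on="respondent_id")

item_cols = [c for c in resp.columns if c.startswith("item_")]
keep = ~resp[item_cols].isna().all(axis=1)
resp = resp[keep]
data = sw.ResponseMatrix.from_dataframe(resp, item_cols)

v = resp["sampling_weight"].to_numpy()
watt = resp["attentiveness_weight"].to_numpy()
fit_cfg = sw.GpcmConfig(max_cycles=300, param_tol=1e-4)
unadjusted = sw.fit_multigroup_gpcm(data, v, fit_cfg)
adjusted = sw.fit_multigroup_gpcm(data, v * watt, fit_cfg)

true_mean = ds.group_distributions[1].mean
print(f"true group-2 latent mean:      {true_mean:.3f}")
print(f"unadjusted estimate:           {unadjusted.groups[1].mean:.3f}")
print(f"adjusted (weighted) estimate:  {adjusted.groups[1].mean:.3f}")

table, summary = sw.compare_fits(adjusted, unadjusted)
print(f"median |mean difference| across groups: "
      f"{summary['median_abs_mean_diff']:.3f}")
print("-> downweighting identified C/IER pulls the group mean back toward "
      "its generating value; the comparison table quantifies the shift.")
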