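"""Per-compound ingestion-excretion budgets and compound fates.

For each caterpillar and compound the budget is
X = W_Leaf*C_Leaf - W_Frass*C_Frass (mg): ~0 means passive excretion,
> 0 loss in the gut, < 0 production in the gut.  Percent losses leaf->frass
summarize each host's chemistry turnover; the retention estimator pools
X/ingested across caterpillars and recovers the generator's truth.
"""

import pandas as pd

from phenobalance import (
    balance_table,
    generate_experiment,
    percent_loss,
    retention_estimates,
)

experiment, truth = generate_experiment(seed=0)
table = balance_table(experiment.phase_records(1), experiment.catalog)

print("fate counts across all Phase-I budget lines:")
print(table["fate"].value_counts().to_string())

# percent loss of geraniin (HH1) on its host: near-total removal in the gut
hh1 = table[(table["current_host"] == "carpinus") & (table["variable"] == "HH1")]
loss = percent_loss(hh1["ingested"].sum(), hh1["excreted"].sum())
print(f"\ngeraniin (HH1) loss leaf->frass on carpinus: {100 * loss:.1f}%")

ox = table[table["variable"] == "Ox"]
for host, sub in ox.groupby("current_host"):
    loss = percent_loss(sub["ingested"].sum(), sub["excreted"].sum())
    print(f"oxidative activity loss on {host}: {100 * loss:.0f}%")

est = retention_estimates(table, experiment.catalog)
rows = []
for (host, cid), row in est.iterrows():
    rows.append(
        {"host": host, "compound": cid, "lambda_hat": row["lambda_hat"],
         "lambda_true": truth.lambda_base[host][cid]}
    )
cmp = pd.DataFrame(rows)
cmp["abs_err"] = (cmp["lambda_hat"] - cmp["lambda_true"]).abs()
print(f"\nretention recovery: {len(cmp)} host x compound estimates, "
      f"max |error| = {cmp['abs_err'].max():.3f}")
print(cmp.nlargest(3, "lambda_true").to_string(index=False,
      float_format=lambda v: f"{v:.3f}"))
# The largest true retentions (hydrolyzable tannins) are recovered within
# a few hundredths despite lognormal measurement noise.
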