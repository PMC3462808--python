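"""Generate synthetic datasets with the two experiments' structure and analyze them.

Experiment-1 structure: 39 participants x 16 conjunction problems about real
unique events (seeded from the published mean conjunct estimates), numeric
0-100 responses, two question orders.  Experiment-2 structure: 18 participants
x 16 trials crossing a verbal and a numeric block with four masked problem
forms.  The analysis pipeline then reports violation rates, strategy rates,
and the model-comparison table.
"""

from probjudge import (
    SimParams,
    compare_models,
    generate_experiment1,
    generate_experiment2,
    strategy_rates,
    violation_summary,
)

params = SimParams(w_mult=0.3, noise_sd=0.05)

exp1 = generate_experiment1(39, params, seed=101)
print(f"experiment-1 structure: {len(exp1)} trials from 39 participants")
overall = violation_summary(exp1)["violation_rate"].iloc[0]
print(f"  JPD violation rate: {overall:.1%}")
print(violation_summary(exp1, ["order"]).to_string(index=False))
mult = strategy_rates(exp1).overall["multiplicative"]
print(f"  multiplication-strategy trials: {mult:.1%}")

print("\nmodel comparison (fits on the proportion scale):")
for name, fit in compare_models(exp1, ["mixture", "wyer", "fantino"]).items():
    print(f"  {name:8s} R^2 = {fit.r_squared:.2f}  RMSE = {fit.rmse:.2f}")

exp2 = generate_experiment2(18, params, seed=202)
print(f"\nexperiment-2 structure: {len(exp2)} trials from 18 participants")
print(violation_summary(exp2, ["scale"]).to_string(index=False))
print("verbal judgments, made on the coarse 7-point scale, violate the JPD less often.")
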