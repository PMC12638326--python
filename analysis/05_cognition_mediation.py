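"""WMBAG-cognition regressions and the mediation battery.

On the same 5000-participant shortcut cohort as script 04: regress the
four cognition composites on the corrected gap (Bonferroni 0.05/4),
then run the factor x outcome mediation battery (gap as mediator,
bootstrap CIs).  Writes results/cognition_regressions.csv and
results/mediation_battery.csv.
"""

from pathlib import Path

import numpy as np

from wmbrainage import assoc, bias, mediate, risk, synth

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

cfg = synth.SynthConfig(n_participants=5000, seed=1)
records, truth = synth.simulate_cohort(cfg)
cognition, _ = synth.simulate_cognition(records, truth, cfg)
splits = synth.make_splits(records, seed=1)
raw = synth.latent_predictions(records, truth, cfg)
val = raw[(splits == "validation").to_numpy()]
bm = bias.fit_bias(val["y"].to_numpy(), val["y_hat"].to_numpy())
preds = bias.predictions_frame(raw, bm)

df = records.join(
    risk.standardise_cognition(cognition).drop(columns=["participant_id", "timepoint"])
)
df = df.merge(preds[["participant_id", "wmbag"]], on="participant_id")

table, _ = assoc.cognition_regressions(df)
table.to_csv(OUT / "cognition_regressions.csv", index=False)
print("WMBAG-cognition betas (alpha_bonf = 0.0125):")
for _, row in table.iterrows():
    star = "*" if row["significant_bonferroni"] else " "
    print(f"  {row['outcome']:<18} b={row['beta_wmbag']:+.4f}  p={row['p']:.2g} {star}")

battery = mediate.mediation_battery(df, n_boot=2000, seed=1)
battery.to_csv(OUT / "mediation_battery.csv", index=False)
sig = battery[battery["acme_significant_bonferroni"]]
print(f"\nmediation battery: {len(battery)} factor x outcome models, "
      f"{len(sig)} significant indirect effects after Bonferroni:")
for _, row in sig.iterrows():
    print(f"  {row['factor']} -> gap -> {row['outcome']}: acme={row['acme']:+.4f} "
          f"[{row['acme_ci_low']:+.4f}, {row['acme_ci_high']:+.4f}]")
print(f"wrote {OUT / 'mediation_battery.csv'}")
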