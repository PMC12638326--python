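"""Vascular-risk association models on a 5000-participant cohort.

Uses the latent-gap shortcut (emulated noisy predictions, bias
corrected on the validation split) so the statistical layer is
exercised at full cohort size without CNN training.  Fits the ANCOVA
group comparison, the VRS main-effect and sex-interaction models, the
five-factor model and the per-factor sex-moderation models, and writes
one tidy CSV per model under results/.
"""

from pathlib import Path

import pandas as pd

from wmbrainage import assoc, bias, risk, synth

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

cfg = synth.SynthConfig(n_participants=5000, seed=1)
records, truth = synth.simulate_cohort(cfg)
splits = synth.make_splits(records, seed=1)
raw = synth.latent_predictions(records, truth, cfg)
val = raw[(splits == "validation").to_numpy()]
bm = bias.fit_bias(val["y"].to_numpy(), val["y_hat"].to_numpy())
preds = bias.predictions_frame(raw, bm)

df = records.join(risk.compute_vrs_frame(records))
df = df.merge(preds[["participant_id", "wmbag"]], on="participant_id")

anc = assoc.ancova_group_difference(df)
print(f"ANCOVA healthy vs unhealthy: adjusted difference "
      f"{anc.beta('group'):+.3f} y (planted {cfg.unhealthy_extra_gap}) p={anc.p('group'):.2g}")

tables = {"ancova": anc}
tables["model_1a"] = assoc.fit_model_1a(df)
tables["model_1b"] = assoc.fit_model_1b(df)
tables["model_2a"] = assoc.fit_model_2a(df)
for k, r in assoc.fit_models_2b_f(df).items():
    tables[f"model_2_{k}"] = r

r1a = tables["model_1a"]
print("model 1a VRS dummies:",
      {k: round(r1a.beta(k), 3) for k in ("vrs_1", "vrs_2", "vrs_3")})
r2a = tables["model_2a"]
print("model 2a factors:",
      {k: round(r2a.beta(k), 3) for k in synth.RISK_FACTORS})
ob = tables["model_2_obesity"]
print(f"obesity x sex: {ob.beta('obesity_x_sex'):+.3f} "
      f"(planted {cfg.sex_obesity_interaction}) p={ob.p('obesity_x_sex'):.2g}")
contrast = assoc.vrs_level_sex_contrast(tables["model_1b"], 3)
print(f"male-female gap at VRS>=3: {contrast['difference']:+.3f} y (p={contrast['p']:.3f})")

for name, res in tables.items():
    res.terms.assign(n_used=res.n_used).reset_index(names="term").to_csv(
        OUT / f"assoc_{name}.csv", index=False
    )
print(f"wrote {len(tables)} model tables under {OUT}/assoc_*.csv")
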