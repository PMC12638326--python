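"""Fit the age-bias model on validation predictions and invert it on test.

Reads results/predictions_raw.csv (from 02_train_brainage.py), fits
y_hat = alpha*y + beta on the validation split, applies
y_hat_co = (y_hat - beta)/alpha to the test split, and reports how the
gap-age correlation collapses while MAE changes only slightly.  Writes
results/bias_correction.csv and results/predictions_corrected.csv.
"""

from pathlib import Path

import pandas as pd

from wmbrainage import bias

OUT = Path(__file__).resolve().parents[1] / "results"
raw = pd.read_csv(OUT / "predictions_raw.csv")

val = raw[raw["split"] == "validation"]
test = raw[raw["split"] == "test"]
model = bias.fit_bias(val["y"].to_numpy(), val["y_hat"].to_numpy())
print(f"bias model: alpha={model.alpha:.3f}, beta={model.beta:.2f}, "
      f"R2={model.fit_r2:.3f} (n={model.n_fit})")

rows = []
for label, sub in (("validation", val), ("test", test)):
    before = bias.performance(sub["y"].to_numpy(), sub["y_hat"].to_numpy())
    corrected = bias.apply_bias(sub["y_hat"].to_numpy(), model)
    after = bias.performance(sub["y"].to_numpy(), corrected)
    rows.append({"split": label, "stage": "raw", "mae": before.mae,
                 "pearson_r": before.pearson_r, "spearman_gap_age": before.spearman_gap_age})
    rows.append({"split": label, "stage": "corrected", "mae": after.mae,
                 "pearson_r": after.pearson_r, "spearman_gap_age": after.spearman_gap_age})
    print(f"{label}: Spearman(gap, age) {before.spearman_gap_age:+.3f} -> "
          f"{after.spearman_gap_age:+.3f}; MAE {before.mae:.2f} -> {after.mae:.2f}")

pd.DataFrame(rows).to_csv(OUT / "bias_correction.csv", index=False)

out = raw.rename(columns={"timepoint": "timepoint"}).copy()
out["timepoint"] = "baseline"
out = bias.predictions_frame(out, model)
out.to_csv(OUT / "predictions_corrected.csv", index=False)
print(f"wrote {OUT / 'bias_correction.csv'}")
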