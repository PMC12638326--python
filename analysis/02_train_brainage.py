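"""Train the five single-map networks and the fusion head at desk scale.

A 400-participant cohort on a 24x28x24 grid with narrow channels: each
of the five maps gets its own eight-block network; the fusion head is
ordinary least squares over the frozen block-7 features plus (sex,
scanner, ICV).  Writes per-map and fused performance to
results/brainage_performance.csv and raw test predictions to
results/predictions_raw.csv.  Takes a few CPU-minutes.
"""

import time
from pathlib import Path

import numpy as np
import pandas as pd

from wmbrainage import bias, synth
from wmbrainage.imgio import MAP_NAMES
from wmbrainage.network import NetworkSpec
from wmbrainage.train import (
    TrainConfig,
    extract_features,
    fit_fusion_head,
    predict_fusion,
    train_single_map,
)

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

cfg = synth.SynthConfig(n_participants=400, seed=0)
records, truth = synth.simulate_cohort(cfg)
vols = synth.render_cohort(records, truth, cfg)
splits = synth.make_splits(records, seed=0)
tr = (splits == "train").to_numpy()
va = (splits == "validation").to_numpy()
te = (splits == "test").to_numpy()
ages, sex = records["age"].to_numpy(), records["sex"].to_numpy()
scanner, icv = records["scanner"].to_numpy(), records["icv"].to_numpy()

spec = NetworkSpec.desk_scale()
tc = TrainConfig(epochs=3, seed=0)
rows, models = [], {}
for m in MAP_NAMES:
    t0 = time.time()
    models[m] = train_single_map(vols[m][tr], ages[tr], sex[tr], scanner[tr], spec, tc, map_label=m)
    pv = models[m].predict(vols[m][va], sex[va], scanner[va])
    rep = bias.performance(ages[va], pv)
    rows.append({"model": m, "split": "validation", "mae": rep.mae, "pearson_r": rep.pearson_r,
                 "train_seconds": time.time() - t0})
    print(f"{m}: validation MAE {rep.mae:.2f} y, r {rep.pearson_r:.3f}")

feats = {s: [extract_features(models[m], vols[m][s_idx]) for m in MAP_NAMES]
         for s, s_idx in (("tr", tr), ("va", va), ("te", te))}
head = fit_fusion_head(feats["tr"], np.column_stack([sex[tr], scanner[tr], icv[tr]]), ages[tr])
for s, idx in (("validation", va), ("test", te)):
    key = "va" if s == "validation" else "te"
    p = predict_fusion(head, feats[key], np.column_stack([sex[idx], scanner[idx], icv[idx]]))
    rep = bias.performance(ages[idx], p)
    rows.append({"model": "fusion", "split": s, "mae": rep.mae, "pearson_r": rep.pearson_r,
                 "train_seconds": np.nan})
    print(f"fusion: {s} MAE {rep.mae:.2f} y, r {rep.pearson_r:.3f}")

pd.DataFrame(rows).to_csv(OUT / "brainage_performance.csv", index=False)

p_te = predict_fusion(head, feats["te"], np.column_stack([sex[te], scanner[te], icv[te]]))
p_va = predict_fusion(head, feats["va"], np.column_stack([sex[va], scanner[va], icv[va]]))
preds = pd.concat([
    pd.DataFrame({"participant_id": records.loc[va, "participant_id"], "split": "validation",
                  "y": ages[va], "y_hat": p_va}),
    pd.DataFrame({"participant_id": records.loc[te, "participant_id"], "split": "test",
                  "y": ages[te], "y_hat": p_te}),
])
preds.to_csv(OUT / "predictions_raw.csv", index=False)
print(f"\nwrote {OUT / 'brainage_performance.csv'} and {OUT / 'predictions_raw.csv'}")
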