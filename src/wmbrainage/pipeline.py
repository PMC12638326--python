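"""End-to-end orchestration: simulate -> train -> predict -> correct -> analyse.

Each stage persists its outputs under the run directory and later
stages read only those artifacts, so every stage can be re-run in
isolation; a missing upstream artifact raises an error naming the
expected file.  One YAML config governs the whole run and every random
consumer derives its stream from the single global seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assoc, bias, imgio, longit, mediate, risk, synth
from .imgio import MAP_NAMES, RISK_FACTORS
from .network import NetworkSpec
from .train import (
    TrainConfig,
    extract_features,
    fit_fusion_head,
    load_fusion_head,
    load_single_map,
    predict_fusion,
    save_fusion_head,
    save_single_map,
    train_single_map,
)

__all__ = ["RunConfig", "run_pipeline", "STAGES"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    outdir: str = "runs/smoke"
    synth: synth.SynthConfig = field(
        default_factory=lambda: synth.SynthConfig(n_participants=120)
    )
    network: NetworkSpec = field(default_factory=NetworkSpec.desk_scale)
    training: TrainConfig = field(default_factory=TrainConfig)
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    n_boot: int = 1000
    do_longitudinal: bool = True
    do_mediation: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        # one global seed drives every stage-level stream
        self.synth = dataclasses.replace(self.synth, seed=self.seed)
        self.training = dataclasses.replace(self.training, seed=self.seed)

    # -- serialisation ------------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "synth" in d:
            sd = dict(d["synth"])
            for k in ("age_range", "grid_shape", "interval_years", "apoe_probs"):
                if k in sd:
                    sd[k] = tuple(sd[k])
            if "cognition_paths" in sd and isinstance(sd["cognition_paths"], dict):
                sd["cognition_paths"] = synth.CognitionPaths(**sd["cognition_paths"])
            d["synth"] = synth.SynthConfig(**sd)
        if "network" in d:
            nd = dict(d["network"])
            for k in ("input_shape", "conv_channels"):
                if k in nd:
                    nd[k] = tuple(nd[k])
            d["network"] = NetworkSpec(**nd)
        if "training" in d:
            d["training"] = TrainConfig(**d["training"])
        if "fractions" in d:
            d["fractions"] = tuple(d["fractions"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def _out(cfg: RunConfig) -> Path:
    p = Path(cfg.outdir)
    p.mkdir(parents=True, exist_ok=True)
    return p


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(f"stage {stage!r} requires missing artifact: {path}")
    return path


# ---------------------------------------------------------------------------
# Stages

def stage_simulate(cfg: RunConfig) -> dict:
    out = _out(cfg)
    records, truth = synth.simulate_cohort(cfg.synth)
    cognition, _ = synth.simulate_cognition(records, truth, cfg.synth)
    splits = synth.make_splits(records, cfg.fractions, seed=cfg.seed)
    records = records.assign(split=splits)

    fu_records = fu_truth = None
    if cfg.do_longitudinal and cfg.synth.longitudinal_fraction > 0:
        fu_records, fu_truth = synth.make_longitudinal_subset(records, truth, cfg.synth)
        fu_cog, _ = synth.simulate_cognition(fu_records, fu_truth, cfg.synth)
        cognition = pd.concat([cognition, fu_cog], ignore_index=True)

    all_records = (
        pd.concat([records, fu_records], ignore_index=True)
        if fu_records is not None
        else records
    )
    all_truth = (
        pd.concat([truth, fu_truth], ignore_index=True) if fu_truth is not None else truth
    )

    vol_dir = out / "volumes"
    merged = all_records.merge(
        all_truth[["participant_id", "timepoint", "true_gap"]],
        on=["participant_id", "timepoint"],
    )
    fields = synth._map_fields(cfg.synth)
    path_cols = {f"path_{m}": [] for m in MAP_NAMES}
    for row in merged.to_dict("records"):
        ms = synth.render_maps(row, row, cfg.synth, _fields=fields)
        paths = imgio.save_map_set(ms, vol_dir)
        for m in MAP_NAMES:
            path_cols[f"path_{m}"].append(str(paths[m]))
    manifest = all_records.merge(cognition, on=["participant_id", "timepoint"])
    for c, vals in path_cols.items():
        manifest[c] = vals
    imgio.write_manifest(manifest, out / "manifest.csv")
    all_truth.to_csv(out / "truth.csv", index=False)
    return {
        "n_baseline": int((all_records["timepoint"] == "baseline").sum()),
        "n_followup": int((all_records["timepoint"] == "followup").sum()),
        "split_counts": records["split"].value_counts().to_dict(),
    }


def _load_volumes(manifest: pd.DataFrame) -> dict[str, np.ndarray]:
    sets = [imgio.load_map_set(row) for _, row in manifest.iterrows()]
    return {m: np.stack([s.volumes[m] for s in sets]).astype(np.float32) for m in MAP_NAMES}


def stage_train(cfg: RunConfig) -> dict:
    out = _out(cfg)
    manifest = imgio.read_manifest(_require(out / "manifest.csv", "train"))
    tr = manifest[(manifest["split"] == "train") & (manifest["timepoint"] == "baseline")]
    vols = _load_volumes(tr)
    ages = tr["age"].to_numpy()
    sex = tr["sex"].to_numpy()
    scanner = tr["scanner"].to_numpy()
    models = {}
    for m in MAP_NAMES:
        t0 = time.time()
        models[m] = train_single_map(
            vols[m], ages, sex, scanner, cfg.network, cfg.training, map_label=m
        )
        log.info("trained %s network in %.1fs", m, time.time() - t0)
        save_single_map(models[m], out / "models" / m)
    feats = [extract_features(models[m], vols[m]) for m in MAP_NAMES]
    cov = np.column_stack([sex, scanner, tr["icv"].to_numpy()])
    head = fit_fusion_head(feats, cov, ages)
    save_fusion_head(head, out / "models" / "fusion.npz")
    return {"final_train_loss": {m: models[m].loss_log[-1] for m in MAP_NAMES}}


def stage_predict(cfg: RunConfig) -> dict:
    out = _out(cfg)
    manifest = imgio.read_manifest(_require(out / "manifest.csv", "predict"))
    models = {m: load_single_map(_require(out / "models" / f"{m}.npz", "predict").with_suffix("")) for m in MAP_NAMES}
    head = load_fusion_head(_require(out / "models" / "fusion.npz", "predict"))
    todo = manifest[(manifest["split"] != "train") | (manifest["timepoint"] == "followup")]
    vols = _load_volumes(todo)
    feats = [extract_features(models[m], vols[m]) for m in MAP_NAMES]
    cov = np.column_stack(
        [todo["sex"].to_numpy(), todo["scanner"].to_numpy(), todo["icv"].to_numpy()]
    )
    y_hat = predict_fusion(head, feats, cov)
    preds = pd.DataFrame(
        {
            "participant_id": todo["participant_id"],
            "timepoint": todo["timepoint"],
            "split": todo["split"],
            "y": todo["age"],
            "y_hat": y_hat,
        }
    )
    preds.to_csv(out / "predictions_raw.csv", index=False)
    return {"n_predicted": int(len(preds))}


def stage_correct(cfg: RunConfig) -> dict:
    out = _out(cfg)
    raw = pd.read_csv(_require(out / "predictions_raw.csv", "correct"))
    val = raw[(raw["split"] == "validation") & (raw["timepoint"] == "baseline")]
    bm = bias.fit_bias(val["y"].to_numpy(), val["y_hat"].to_numpy())
    preds = bias.predictions_frame(raw, bm)
    preds.to_csv(out / "predictions.csv", index=False)
    (out / "bias_model.json").write_text(json.dumps(dataclasses.asdict(bm), indent=2))
    perf = {}
    for split in ("validation", "test"):
        sub = preds[(preds["split"] == split) & (preds["timepoint"] == "baseline")]
        if len(sub) >= 2:
            perf[split] = dataclasses.asdict(
                bias.performance(sub["y"].to_numpy(), sub["y_hat_co"].to_numpy())
            )
    (out / "performance.json").write_text(json.dumps(perf, indent=2))
    return {"bias": dataclasses.asdict(bm), "performance": perf}


def stage_analyse(cfg: RunConfig) -> dict:
    out = _out(cfg)
    manifest = imgio.read_manifest(_require(out / "manifest.csv", "analyse"), check_paths=False)
    preds = pd.read_csv(_require(out / "predictions.csv", "analyse"))

    base = manifest[manifest["timepoint"] == "baseline"].copy()
    base = base.join(risk.compute_vrs_frame(base))
    cog_cols = [c for c in imgio.COGNITION_TESTS if c in base.columns]
    base = base.join(
        risk.standardise_cognition(base[cog_cols]).drop(
            columns=["participant_id", "timepoint"], errors="ignore"
        )
    )
    test_base = preds[(preds["timepoint"] == "baseline") & (preds["split"] == "test")]
    df = base.merge(
        test_base[["participant_id", "y_hat_co", "wmbag"]], on="participant_id"
    )

    summary: dict = {}
    tables: dict[str, pd.DataFrame] = {}

    res_ancova = assoc.ancova_group_difference(df)
    tables["ancova"] = res_ancova.terms.reset_index(names="term")
    summary["ancova_group_difference"] = res_ancova.beta("group")

    for name, fn in (("model_1a", assoc.fit_model_1a), ("model_1b", assoc.fit_model_1b), ("model_2a", assoc.fit_model_2a)):
        r = fn(df)
        tables[name] = r.terms.reset_index(names="term")
    for k, r in assoc.fit_models_2b_f(df).items():
        tables[f"model_2_{k}"] = r.terms.reset_index(names="term")

    cog_table, _ = assoc.cognition_regressions(df)
    tables["cognition_regressions"] = cog_table

    if cfg.do_mediation:
        tables["mediation"] = mediate.mediation_battery(
            df, n_boot=cfg.n_boot, seed=cfg.seed
        )

    if cfg.do_longitudinal:
        fu = preds[preds["timepoint"] == "followup"]
        if len(fu):
            bl = preds[
                (preds["timepoint"] == "baseline")
                & preds["participant_id"].isin(fu["participant_id"])
            ]
            cog_all = manifest
            cb = risk.standardise_cognition(
                cog_all[cog_all["timepoint"] == "baseline"][
                    ["participant_id", *cog_cols]
                ],
            )
            cf = risk.standardise_cognition(
                cog_all[cog_all["timepoint"] == "followup"][
                    ["participant_id", *cog_cols]
                ],
            )
            changes = longit.change_scores(bl, fu, cb, cf)
            t = longit.paired_t(changes["delta_wmbag"].to_numpy())
            summary["longitudinal"] = {
                "n_pairs": int(len(changes)),
                "mean_delta_wmbag": t.mean_change,
                "paired_t": t.t,
                "paired_p": t.p,
                "percent_predicted_age_increased": longit.percent_increased(
                    changes["delta_predicted_age"].to_numpy()
                ),
            }
            ch = longit.change_regressions_and_mediation(
                df, changes, n_boot=cfg.n_boot, seed=cfg.seed,
                do_mediation=cfg.do_mediation,
            )
            for k, v in ch.items():
                tables[f"longitudinal_{k}"] = v

    tdir = out / "tables"
    tdir.mkdir(exist_ok=True)
    for name, t in tables.items():
        t.to_csv(tdir / f"{name}.csv", index=False)
    summary["tables"] = sorted(tables)
    return summary


STAGES = {
    "simulate": stage_simulate,
    "train": stage_train,
    "predict": stage_predict,
    "correct": stage_correct,
    "analyse": stage_analyse,
}


def run_pipeline(cfg: RunConfig) -> dict:
    """Run all stages; returns (and writes) the machine-readable summary."""
    out = _out(cfg)
    cfg.to_yaml(out / "config.yaml")
    summary = {
        "config_hash": cfg.config_hash,
        "seed": cfg.seed,
        "stages": {},
    }
    timings = {}
    for name, fn in STAGES.items():
        t0 = time.time()
        try:
            summary["stages"][name] = fn(cfg)
        except Exception:
            (out / "summary_partial.json").write_text(
                json.dumps(summary, indent=2, default=str)
            )
            log.error("pipeline halted in stage %r", name)
            raise
        timings[name] = time.time() - t0
        log.info("stage %s finished in %.1fs", name, timings[name])
    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
    (out / "timings.json").write_text(json.dumps(timings, indent=2))
    return summary
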