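"""Configuration-driven orchestration of the full synthetic study.

``run_pipeline`` executes generate -> cluster -> train -> evaluate/flag ->
classify -> mechanics from a single seeded :class:`RunConfig`, writing CSV/
JSON artifacts and a manifest with SHA-256 hashes.  Stage seeds are fanned
out deterministically from the global seed so toggling one stage never
changes another's output.  A stage failure is recorded in the manifest
(status "failed", later stages "skipped") before the error propagates.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import aberrance, classifier, mechanics, som, studies, synthetic, yapnet

log = logging.getLogger("morphomech")

_STAGES = ("generate", "cluster", "train_yap", "evaluate", "classify", "mechanics")


@dataclass
class RunConfig:
    seed: int
    outdir: str = "morphomech_run"
    n_per_archetype: int = 100
    explainable_variance: float = 0.65
    z_threshold: float = 2.0
    stages: dict = field(default_factory=lambda: {s: True for s in _STAGES})
    input_table: str | None = None  # skip generation, read this CSV instead

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        if "seed" not in d:
            raise ValueError("config must specify a seed")
        cfg = cls(seed=int(d["seed"]))
        for k, v in d.items():
            if k == "stages":
                cfg.stages.update(v)
            elif hasattr(cfg, k):
                setattr(cfg, k, v)
            else:
                raise ValueError(f"unknown config key: {k}")
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage


def run_pipeline(config: RunConfig) -> dict:
    """Run all enabled stages; returns (and writes) the manifest dict."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "config": {
            "n_per_archetype": config.n_per_archetype,
            "explainable_variance": config.explainable_variance,
            "z_threshold": config.z_threshold,
            "stages": dict(config.stages),
        },
        "stages": {},
        "artifacts": {},
    }

    def record(name: str, path: Path):
        manifest["artifacts"][name] = {
            "path": str(path.relative_to(out)),
            "sha256": _sha256(path),
        }

    def finish(stage: str, status: str, error: str | None = None):
        manifest["stages"][stage] = {"status": status}
        if error:
            manifest["stages"][stage]["error"] = error

    table = None
    yap_model = None
    errors = None
    state: dict = {}
    failed: Exception | None = None
    failed_stage = ""
    for stage in _STAGES:
        if failed is not None or not config.stages.get(stage, True):
            finish(stage, "skipped")
            continue
        s = stage_seed(config.seed, stage)
        try:
            if stage == "generate":
                if config.input_table:
                    table = synthetic.read_table(config.input_table)
                else:
                    base = synthetic.CouplingSpec()
                    pop = synthetic.generate_population(
                        n_per_archetype=config.n_per_archetype, seed=s
                    )
                    noise = synthetic.noise_sd_for_explainable_variance(
                        pop, base, config.explainable_variance
                    )
                    table, _ = synthetic.assign_yap(
                        pop, synthetic.CouplingSpec(noise_sd=noise), seed=s + 1
                    )
                synthetic.write_table(table, out / "table.csv")
                record("table", out / "table.csv")
            elif stage == "cluster":
                model = som.train_som(table, seed=s)
                model.to_json(out / "som.json")
                assign = som.assign_clusters(model, table)
                pd.DataFrame(
                    {"cell_id": table["cell_id"], "cluster": assign}
                ).to_csv(out / "assignments.csv", index=False)
                record("som", out / "som.json")
                record("assignments", out / "assignments.csv")
            elif stage == "train_yap":
                y = table["yap_ratio"].to_numpy()
                tr, te = yapnet.split_data(len(table), 0.75, seed=s)
                keep = aberrance.grubbs_filter(y[tr]).kept
                kept_mask = np.isin(y[tr], keep)
                X = table[synthetic.FEATURE_COLUMNS]
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    yap_model = yapnet.train_bayesian_mlp(
                        X.iloc[tr[kept_mask]], y[tr][kept_mask], seed=s + 1
                    )
                yap_model.to_json(out / "yap_model.json")
                pred = yapnet.predict_yap(yap_model, X)
                split = np.where(np.isin(np.arange(len(table)), tr), "train", "test")
                pd.DataFrame(
                    {
                        "cell_id": table["cell_id"],
                        "split": split,
                        "measured": y,
                        "predicted": pred,
                    }
                ).to_csv(out / "predictions.csv", index=False)
                record("yap_model", out / "yap_model.json")
                record("predictions", out / "predictions.csv")
                state["split"] = split
            elif stage == "evaluate":
                pred_df = pd.read_csv(out / "predictions.csv")
                errors = pred_df["measured"] - pred_df["predicted"]
                train_sel = pred_df["split"] == "train"
                ref_sigma = float(errors[train_sel].std(ddof=1))
                flags, frac = aberrance.flag_decoupled(
                    errors, ref_sigma, config.z_threshold, groups=table["group"]
                )
                stats = aberrance.group_error_stats(
                    errors, table["group"], ref_sigma, config.z_threshold
                )
                comparison = aberrance.compare_group_errors(errors, table["group"])
                payload = {
                    "reference_sigma": ref_sigma,
                    "z_threshold": config.z_threshold,
                    "kruskal_h": comparison.h_statistic,
                    "kruskal_p": comparison.p_value,
                    "groups": stats.reset_index().to_dict(orient="records"),
                    "dunn": comparison.posthoc.to_dict(orient="records"),
                }
                (out / "error_stats.json").write_text(
                    json.dumps(payload, indent=1, sort_keys=True)
                )
                pd.DataFrame(
                    {
                        "cell_id": table["cell_id"],
                        "group": table["group"],
                        "error": errors,
                        "flagged": flags,
                    }
                ).to_csv(out / "flags.csv", index=False)
                record("error_stats", out / "error_stats.json")
                record("flags", out / "flags.csv")
            elif stage == "classify":
                res = studies.classifier_study(seed=s)
                rows = []
                for mode in classifier.MODES:
                    res[mode]["model"].to_json(out / f"classifier_{mode}.json")
                    record(f"classifier_{mode}", out / f"classifier_{mode}.json")
                    rows.append(
                        {
                            "mode": mode,
                            "accuracy": res[mode]["accuracy"],
                            "false_negative_rate": res[mode]["fnr"],
                        }
                    )
                pd.DataFrame(rows).to_csv(out / "confusion.csv", index=False)
                record("confusion", out / "confusion.csv")
            elif stage == "mechanics":
                rec = studies.mechanics_recovery_study(seed=s)
                payload = {
                    "A": rec["fit"].A,
                    "B": rec["fit"].B,
                    "k_matrix": rec["fit"].k_matrix,
                    "sigma0": rec["org"].sigma0,
                    "sigma_inf": rec["org"].sigma_inf,
                    "alpha": rec["org"].alpha,
                    "theta0": rec["org"].theta0,
                    "r_squared": rec["r_squared"],
                }
                (out / "mechanics_params.json").write_text(
                    json.dumps(payload, indent=1, sort_keys=True)
                )
                record("mechanics_params", out / "mechanics_params.json")
            finish(stage, "ok")
        except Exception as exc:  # noqa: BLE001 - manifest must record any failure
            log.error("stage %s failed: %s", stage, exc)
            finish(stage, "failed", str(exc))
            failed, failed_stage = exc, stage

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    if failed is not None:
        raise PipelineError(failed_stage, failed)
    return manifest


def render_prediction_card(
    cell_mask,
    nucleus_mask,
    measured_ratio: float,
    predicted_ratio: float,
    cytoplasm_level: float = 100.0,
    path=None,
) -> np.ndarray:
    """Side-by-side measured/predicted intensity card on a [0, 255] scale.

    Both panels fill the cytoplasm at the measured cytoplasmic level; the
    nucleus is filled at ratio x cytoplasm, clipped to [0, 255] (left panel:
    measured ratio, right panel: predicted).  Non-positive predictions clip
    to 0 with a warning.  Returns the uint8 image; writes a PNG if ``path``.
    """
    cell = np.asarray(cell_mask) > 0
    nuc = np.asarray(nucleus_mask) > 0
    if predicted_ratio <= 0:
        warnings.warn("non-positive predicted ratio clipped to 0", stacklevel=2)

    def panel(ratio):
        img = np.zeros(cell.shape, float)
        img[cell] = np.clip(cytoplasm_level, 0, 255)
        img[nuc] = np.clip(ratio * cytoplasm_level, 0, 255)
        return img

    card = np.concatenate([panel(measured_ratio), panel(predicted_ratio)], axis=1)
    card = card.astype(np.uint8)
    if path is not None:
        import imageio.v3 as iio

        iio.imwrite(path, card)
    return card
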