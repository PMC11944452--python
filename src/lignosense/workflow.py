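"""End-to-end orchestration: simulate → preprocess → train generators →
augment → train predictor → predict → evaluate.

One seeded :class:`ExperimentConfig` drives the whole pipeline.  Per-stage
seeds derive from the global seed by a fixed offset scheme (documented in
``STAGE_SEED_OFFSETS``) so stages are individually reproducible without
seed collisions.  Every artifact is written under ``output_dir`` and a
manifest records the config hash, stage seeds and artifact checksums;
identical configs produce identical manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    CompositionVector,
    SampleTriplet,
    StateError,
    ValidationError,
)
from .evaluation import (
    MetricRow,
    evaluate_generation,
    evaluate_prediction,
    linear_interpolate,
    mae,
    make_report,
)
from .generators import (
    DEFAULT_AUGMENT_TEMPS,
    GeneratorSpec,
    TrainConfig,
    augment_dataset,
    build_generator,
    generate_at_temperature,
    modality_target,
    train_generator,
)
from .io import save_bundle
from .mvae import MVAEMoE, MVAEMoEConfig, predict_gcms, train_predictor
from .preprocessing import (
    PreprocessConfig,
    preprocessing_information_loss,
    process_bundle,
)
from .synthetic import (
    DEFAULT_ANCHOR_TEMPS,
    GroundTruthOracle,
    SimulatorParams,
    simulate_study,
)

__all__ = [
    "ExperimentConfig",
    "RunResult",
    "run_full_experiment",
    "compare_to_baselines",
    "STAGE_SEED_OFFSETS",
]

logger = logging.getLogger("lignosense.workflow")

STAGE_SEED_OFFSETS = {
    "simulate": 0,
    "train_generator_tga": 101,
    "train_generator_ftir": 102,
    "train_generator_gcms": 103,
    "train_predictor": 201,
}

STAGES = (
    "simulate",
    "preprocess",
    "train_generators",
    "augment",
    "train_predictor",
    "predict",
    "evaluate",
)


@dataclass
class ExperimentConfig:
    simulator: SimulatorParams = field(default_factory=SimulatorParams)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    generator_train: TrainConfig = field(default_factory=TrainConfig)
    predictor_train: TrainConfig = field(default_factory=TrainConfig)
    model: MVAEMoEConfig = field(default_factory=MVAEMoEConfig)
    anchor_temps: tuple[float, ...] = DEFAULT_ANCHOR_TEMPS
    augment_temps: tuple[float, ...] = DEFAULT_AUGMENT_TEMPS
    evaluation_mode: str = "interpolation"  # or "oracle"
    global_seed: int = 0
    output_dir: str = "lignosense_run"

    def __post_init__(self) -> None:
        lo, hi = min(self.anchor_temps), max(self.anchor_temps)
        for t in self.augment_temps:
            if not (lo <= t <= hi):
                raise ValidationError(
                    f"ExperimentConfig: augment temp {t} not bracketed by anchors"
                )
        if self.evaluation_mode not in ("interpolation", "oracle"):
            raise ValidationError("ExperimentConfig: bad evaluation_mode")

    def stage_seed(self, stage: str) -> int:
        return (int(self.global_seed) + STAGE_SEED_OFFSETS[stage]) % (2**31)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class RunResult:
    cfg: ExperimentConfig
    manifest: dict
    oracle: GroundTruthOracle
    anchor_triplets: list[SampleTriplet]
    generated_triplets: list[SampleTriplet]
    generators: dict
    predictor: MVAEMoE
    predictor_history: list
    predictions: dict[float, CompositionVector]
    generation_rows: dict[str, list[MetricRow]]
    prediction_rows: list[MetricRow]
    audit: dict[float, float]


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_hash(cfg: ExperimentConfig) -> str:
    d = cfg.to_dict()
    d.pop("output_dir", None)  # where a run lands must not change its identity
    blob = json.dumps(d, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()


def _write_history_csv(history, path: Path) -> None:
    if isinstance(history, list):
        df = pd.DataFrame(
            [
                {
                    "epoch": i + 1,
                    "recon_tga": b.recon_tga,
                    "recon_ftir": b.recon_ftir,
                    "pred": b.pred,
                    "kl": b.kl,
                    "total": b.total,
                }
                for i, b in enumerate(history)
            ]
        )
    else:
        df = pd.DataFrame(
            {"epoch": np.arange(1, len(history.loss) + 1), "loss": history.loss,
             "lr": history.lr}
        )
    df.to_csv(path, index=False, float_format="%.17g")


def run_full_experiment(cfg: ExperimentConfig) -> RunResult:
    """Execute the full pipeline under one seeded configuration.

    Stage errors propagate annotated with the stage name.  Returns the
    in-memory artifacts plus the written manifest.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    completed: list[dict] = []
    artifacts: list[Path] = []

    def run_stage(name, fn):
        logger.info("stage %s: starting", name)
        try:
            result = fn()
        except Exception as exc:  # annotate with stage name, then re-raise
            raise type(exc)(f"[stage {name}] {exc}") from exc
        completed.append({"stage": name})
        logger.info("stage %s: done", name)
        return result

    # 1. simulate ------------------------------------------------------------
    def _simulate():
        bundle, oracle = simulate_study(
            cfg.anchor_temps, cfg.simulator, cfg.stage_seed("simulate")
        )
        save_bundle(bundle, out / "raw")
        artifacts.extend(sorted((out / "raw").glob("*")))
        return bundle, oracle

    bundle, oracle = run_stage("simulate", _simulate)

    # 2. preprocess ----------------------------------------------------------
    def _preprocess():
        triplets = process_bundle(bundle, cfg.preprocess)
        audit = {}
        resampled = {t.htl_temperature_c: t.tga for t in triplets}
        for raw in bundle["thermograms"]:
            audit[raw.htl_temperature_c] = preprocessing_information_loss(
                raw, resampled[raw.htl_temperature_c], cfg.preprocess
            )
        proc_dir = out / "processed"
        proc_dir.mkdir(exist_ok=True)
        comp_records = {
            "compositions": [(t.htl_temperature_c, t.gcms) for t in triplets]
        }
        save_bundle(comp_records, proc_dir)
        for t in triplets:
            tag = f"{t.htl_temperature_c:g}".replace(".", "p")
            pd.DataFrame(
                {"temperature_c": t.tga.grid_c, "mass_pct": t.tga.mass_pct}
            ).to_csv(proc_dir / f"tga_resampled_{tag}.csv", index=False,
                     float_format="%.17g")
            pd.DataFrame({"value": t.ftir.values}).to_csv(
                proc_dir / f"ftir_preprocessed_{tag}.csv", index=False,
                float_format="%.17g")
        artifacts.extend(sorted(proc_dir.glob("*")))
        return triplets, audit

    anchor_triplets, audit = run_stage("preprocess", _preprocess)

    # 3. train generators ----------------------------------------------------
    def _train_generators():
        models = {}
        tga_dim = cfg.preprocess.tga_clip_high_c - cfg.preprocess.tga_clip_low_c + 1
        dims = {"TGA": tga_dim, "FTIR": 3476, "GCMS": 10}
        gen_dir = out / "generators"
        gen_dir.mkdir(exist_ok=True)
        for modality in ("TGA", "FTIR", "GCMS"):
            spec = GeneratorSpec.for_modality(modality, dims[modality])
            seed = cfg.stage_seed(f"train_generator_{modality.lower()}")
            model = build_generator(spec, seed)
            pairs = [
                (t.htl_temperature_c, modality_target(t, modality))
                for t in anchor_triplets
            ]
            gcfg = dataclasses.replace(cfg.generator_train, seed=seed)
            model, history = train_generator(model, pairs, gcfg)
            models[modality] = model
            _write_history_csv(history, gen_dir / f"loss_{modality.lower()}.csv")
        artifacts.extend(sorted(gen_dir.glob("*")))
        return models

    generators = run_stage("train_generators", _train_generators)

    # 4. augment -------------------------------------------------------------
    def _augment():
        triplets = augment_dataset(generators, cfg.augment_temps)
        gen_dir = out / "augmented"
        gen_dir.mkdir(exist_ok=True)
        save_bundle(
            {"compositions": [(t.htl_temperature_c, t.gcms) for t in triplets]},
            gen_dir,
        )
        artifacts.extend(sorted(gen_dir.glob("*")))
        return triplets

    generated_triplets = run_stage("augment", _augment)

    # 5. train predictor -----------------------------------------------------
    def _train_predictor():
        data = anchor_triplets + generated_triplets
        tga_dim = anchor_triplets[0].tga.mass_pct.size
        mcfg = dataclasses.replace(
            cfg.model, tga_dim=tga_dim, seed=cfg.stage_seed("train_predictor")
        )
        pcfg = dataclasses.replace(
            cfg.predictor_train, seed=cfg.stage_seed("train_predictor")
        )
        model, history = train_predictor(data, pcfg, mcfg)
        pred_dir = out / "predictor"
        pred_dir.mkdir(exist_ok=True)
        _write_history_csv(history, pred_dir / "loss.csv")
        artifacts.append(pred_dir / "loss.csv")
        return model, history

    predictor, predictor_history = run_stage("train_predictor", _train_predictor)

    # 6. predict -------------------------------------------------------------
    def _predict():
        preds = {}
        for t in generated_triplets:
            preds[t.htl_temperature_c] = predict_gcms(predictor, t.tga, t.ftir)
        pred_dir = out / "predictor"
        save_bundle({"compositions": sorted(preds.items())}, pred_dir)
        artifacts.extend(sorted(pred_dir.glob("compositions.csv")))
        return preds

    predictions = run_stage("predict", _predict)

    # 7. evaluate ------------------------------------------------------------
    def _evaluate():
        anchors_by_modality = {
            m: {t.htl_temperature_c: modality_target(t, m) for t in anchor_triplets}
            for m in ("TGA", "FTIR", "GCMS")
        }
        generated_by_modality = {
            m: {t.htl_temperature_c: modality_target(t, m) for t in generated_triplets}
            for m in ("TGA", "FTIR", "GCMS")
        }
        generation_rows = {
            m: evaluate_generation(
                generated_by_modality[m], anchors_by_modality[m], cfg.augment_temps
            )
            for m in ("TGA", "FTIR", "GCMS")
        }
        if cfg.evaluation_mode == "oracle":
            references = {
                t: oracle.composition(t) for t in cfg.augment_temps
            }
        else:
            anchor_comps = anchors_by_modality["GCMS"]
            references = {}
            for t in cfg.augment_temps:
                temps = sorted(anchor_comps)
                lo = max(a for a in temps if a <= t)
                hi = min(a for a in temps if a >= t)
                if lo == hi:
                    references[t] = CompositionVector(anchor_comps[lo])
                else:
                    references[t] = CompositionVector(
                        linear_interpolate(lo, anchor_comps[lo], hi, anchor_comps[hi], t)
                    )
        prediction_rows = evaluate_prediction(predictions, references)
        written = make_report(generation_rows, prediction_rows, audit, out / "report")
        artifacts.extend(written)
        return generation_rows, prediction_rows

    generation_rows, prediction_rows = run_stage("evaluate", _evaluate)

    manifest = {
        "config_hash": _config_hash(cfg),
        "global_seed": cfg.global_seed,
        "stage_seeds": {s: cfg.stage_seed(s) for s in STAGE_SEED_OFFSETS},
        "stages": [c["stage"] for c in completed],
        "checksums": {
            str(p.relative_to(out)): _hash_file(p)
            for p in sorted(set(artifacts))
            if p.is_file()
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return RunResult(
        cfg=cfg,
        manifest=manifest,
        oracle=oracle,
        anchor_triplets=anchor_triplets,
        generated_triplets=generated_triplets,
        generators=generators,
        predictor=predictor,
        predictor_history=predictor_history,
        predictions=predictions,
        generation_rows=generation_rows,
        prediction_rows=prediction_rows,
        audit=audit,
    )


def compare_to_baselines(result: RunResult) -> pd.DataFrame:
    """Predictor MAE vs. two baselines against the simulator oracle.

    Baselines: (a) the constant global-mean composition of the training
    set; (b) linear interpolation of the measured anchor compositions.
    One row per held-out temperature; inputs to the predictor are the
    oracle's noiseless TGA/FT-IR vectors at that temperature.
    """
    if not result.predictor.trained:
        raise StateError("compare_to_baselines: predictor not trained")
    train_comps = np.stack(
        [t.gcms.fractions for t in result.anchor_triplets + result.generated_triplets]
    )
    mean_comp = train_comps.mean(axis=0)
    anchor_comps = {
        t.htl_temperature_c: t.gcms.fractions for t in result.anchor_triplets
    }
    temps = sorted(anchor_comps)
    rows = []
    for t in result.cfg.augment_temps:
        ref = result.oracle.composition(t).fractions
        trip = result.oracle.triplet(t)
        pred = predict_gcms(result.predictor, trip.tga, trip.ftir).fractions
        lo = max(a for a in temps if a <= t)
        hi = min(a for a in temps if a >= t)
        interp = (
            anchor_comps[lo]
            if lo == hi
            else linear_interpolate(lo, anchor_comps[lo], hi, anchor_comps[hi], t)
        )
        rows.append(
            {
                "temperature_c": t,
                "predictor_mae": mae(ref, pred),
                "mean_baseline_mae": mae(ref, mean_comp),
                "interpolation_baseline_mae": mae(ref, interp),
            }
        )
    return pd.DataFrame(rows)
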