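"""End-to-end orchestration: simulate -> quantify -> stats -> model -> fret.

A single config (YAML-friendly dataclass) toggles stages, carries
per-stage seeds and paths, and every run emits a JSON manifest listing
each artifact with a SHA-256 content hash, so reruns with identical
config and seeds can be verified bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .deepsniper_model import OnTargetConfig, TrainingRun, build_model
from .deepsniper_model import encode_on_target, predict as model_predict, train as model_train
from .indel_quant import QuantConfig, apply_filters, merge_replicates
from .library_model import write_library_tsv
from .smfret_unwind import analyze_traces, traces_to_table
from .specificity_stats import (
    annotation_frame,
    pam_profile,
    positionwise_specificity,
    specificity_table,
    stratify_by_mismatch,
    tradeoff_summary,
)
from .synthetic_data import (
    FretPopulationSpec,
    LibraryDesignSpec,
    build_library,
    default_landscape,
    landscape_activity,
    simulate_counts,
    simulate_traces,
    truth_from_landscape,
)

logger = logging.getLogger("sniperkit")

__all__ = ["RunConfig", "run", "load_config"]


class ConfigError(ValueError):
    """A stage's inputs are missing or inconsistent."""


@dataclass
class RunConfig:
    out_dir: str = "results/run"
    stages: list[str] = field(default_factory=list)  # subset of the five below
    n_guides: int = 30
    mismatch_targets_per_guide: int = 20
    depth: float = 1000.0
    background_pct: float = 1.0
    n_molecules: int = 2000
    n_train: int = 2000
    train_epochs: int = 5
    f_unwound_true: float = 0.7
    seeds: dict = field(
        default_factory=lambda: {
            "simulate": 1,
            "quantify": 2,
            "train": 3,
            "fret": 4,
        }
    )
    quant: QuantConfig = field(default_factory=QuantConfig)
    log_level: str = "INFO"

    KNOWN_STAGES = ("simulate", "quantify", "stats", "train", "fret")


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    quant = QuantConfig(**raw.pop("quant", {}))
    return RunConfig(quant=quant, **raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run(config: RunConfig) -> dict:
    """Execute the enabled stages in dependency order and return the
    manifest (also written to ``<out_dir>/manifest.json``)."""
    logging.basicConfig(level=config.log_level)
    unknown = set(config.stages) - set(RunConfig.KNOWN_STAGES)
    if unknown:
        raise ConfigError(f"unknown stages: {sorted(unknown)}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    summaries: dict[str, dict] = {}

    def _register(name: str, path: Path) -> None:
        artifacts[name] = _sha256(path)

    state: dict = {}
    for stage in RunConfig.KNOWN_STAGES:
        if stage not in config.stages:
            continue
        logger.info("stage %s", stage)
        if stage == "simulate":
            _stage_simulate(config, out, state, _register, summaries)
        elif stage == "quantify":
            _require(state, "pairs", "quantify", out / "library.tsv")
            _stage_quantify(config, out, state, _register, summaries)
        elif stage == "stats":
            _require(state, "filtered", "stats", out / "frequencies.tsv")
            _stage_stats(config, out, state, _register, summaries)
        elif stage == "train":
            _stage_train(config, out, state, _register, summaries)
        elif stage == "fret":
            _stage_fret(config, out, state, _register, summaries)

    manifest = {
        "version": __version__,
        "config": _config_dict(config),
        "seeds": config.seeds,
        "stages": config.stages,
        "artifacts": artifacts,
        "summaries": summaries,
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _config_dict(config: RunConfig) -> dict:
    d = asdict(config)
    return d


def _require(state: dict, key: str, stage: str, path: Path) -> None:
    if key in state:
        return
    raise ConfigError(
        f"stage {stage!r} needs {key!r} from an earlier stage or file {path}"
    )


def _stage_simulate(config, out, state, register, summaries) -> None:
    seed = config.seeds.get("simulate", 0)
    spec = LibraryDesignSpec(
        n_guides=config.n_guides,
        mismatch_targets_per_guide=config.mismatch_targets_per_guide,
    )
    pairs = build_library(spec, seed=seed)
    landscape = default_landscape()
    truth = truth_from_landscape(
        pairs, landscape, background_pct=config.background_pct, seed=seed
    )
    counts = simulate_counts(pairs, truth, depth=config.depth, seed=seed + 1)
    write_library_tsv(pairs, out / "library.tsv")
    truth.to_csv(out / "truth.tsv", sep="\t")
    counts.to_csv(out / "counts.tsv", sep="\t", index=False)
    register("library.tsv", out / "library.tsv")
    register("truth.tsv", out / "truth.tsv")
    register("counts.tsv", out / "counts.tsv")
    state.update(pairs=pairs, truth=truth, counts=counts, landscape=landscape)
    summaries["simulate"] = {"n_pairs": len(pairs)}


def _stage_quantify(config, out, state, register, summaries) -> None:
    counts = state["counts"]
    pooled = merge_replicates(counts)
    filtered = apply_filters(pooled, config.quant)
    filtered.to_csv(out / "frequencies.tsv", sep="\t", index=False)
    register("frequencies.tsv", out / "frequencies.tsv")
    state["filtered"] = filtered
    summaries["quantify"] = {
        "n_records": int(len(filtered)),
        "n_passed": int(filtered["passed_filters"].sum()),
    }


def _stage_stats(config, out, state, register, summaries) -> None:
    filtered = state["filtered"]
    passed = filtered[filtered["passed_filters"]]
    ann = annotation_frame(state["pairs"])
    spec_table = specificity_table(passed, ann)
    profile = positionwise_specificity(spec_table)
    strata = stratify_by_mismatch(spec_table)
    per_pam4, per_class = pam_profile(passed.merge(ann[["pair_id"]], on="pair_id"), ann)
    points = tradeoff_summary(passed, spec_table, ann)
    spec_table.to_csv(out / "specificity.tsv", sep="\t", index=False)
    profile.to_csv(out / "position_profile.tsv", sep="\t", index=False)
    strata.to_csv(out / "mismatch_strata.tsv", sep="\t", index=False)
    per_class.to_csv(out / "pam_classes.tsv", sep="\t", index=False)
    for name in (
        "specificity.tsv",
        "position_profile.tsv",
        "mismatch_strata.tsv",
        "pam_classes.tsv",
    ):
        register(name, out / name)
    summaries["stats"] = {
        "n_specificity_records": int(len(spec_table)),
        "tradeoff": [asdict(p) for p in points],
    }


def _stage_train(config, out, state, register, summaries) -> None:
    seed = config.seeds.get("train", 0)
    landscape = state.get("landscape", default_landscape())
    rng = np.random.default_rng(seed)
    spec = LibraryDesignSpec(
        n_guides=config.n_train, mismatch_targets_per_guide=0
    )
    pairs = build_library(spec, seed=seed)
    x = np.stack([encode_on_target(p.context, p.expression_system)[0] for p in pairs])
    flags = np.array(
        [encode_on_target(p.context, p.expression_system)[1] for p in pairs]
    )
    y = np.array([landscape_activity(p, landscape) for p in pairs])
    n_val = max(len(y) // 5, 1)
    val = rng.choice(len(y), size=n_val, replace=False)
    mask = np.zeros(len(y), dtype=bool)
    mask[val] = True
    run_cfg = TrainingRun(epochs=config.train_epochs, seed=seed)
    model = build_model(OnTargetConfig(), seed=seed)
    model_train(
        model, x[~mask], flags[~mask], y[~mask], run_cfg,
        x_val=x[mask], aux_val=flags[mask], y_val=y[mask],
    )
    pred = model_predict(model, x[mask], flags[mask])
    from scipy import stats as sstats

    r = float(sstats.pearsonr(pred, y[mask])[0]) if n_val > 2 else float("nan")
    hist = pd.DataFrame(run_cfg.history)
    hist.to_csv(out / "training_history.tsv", sep="\t", index=False)
    register("training_history.tsv", out / "training_history.tsv")
    summaries["train"] = {
        "n_train": int((~mask).sum()),
        "n_val": int(mask.sum()),
        "val_pearson": r,
        "final_train_mae": float(hist["train_mae"].iloc[-1]),
    }


def _stage_fret(config, out, state, register, summaries) -> None:
    seed = config.seeds.get("fret", 0)
    spec = FretPopulationSpec(f_unwound_true=config.f_unwound_true)
    traces = simulate_traces(spec, config.n_molecules, seed=seed)
    table = traces_to_table(traces)
    table.to_csv(out / "traces.tsv", sep="\t", index=False)
    register("traces.tsv", out / "traces.tsv")
    summaries["fret"] = analyze_traces(traces)
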