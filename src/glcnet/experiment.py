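"""End-to-end experiment runner: config, orchestration, reports.

One :func:`run_experiment` call executes the full pipeline on a dataset
(file or synthetic spec): stratified split, adjacency estimation on the
training partition only, filter-bank decomposition, model construction,
two-stage training, evaluation, and report writing.  With an ablation
list it repeats the run per removed module and writes a comparison table
(accuracy / kappa / F1 per variant).

Every run directory receives a manifest (full resolved config, all
seeds, package versions) sufficient to reproduce the run bit-identically
on the same platform.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from .core_data import ConfigurationError, EpochSet, SplitSpec, load_epochs, split_epochs
from .filterbank import FilterBankSpec, apply_filterbank, make_default_bank
from .graph import (
    AdjacencySpec,
    adjacency_from_csv,
    compute_distance_adjacency,
    compute_pli_adjacency,
)
from .model import Model, ModelConfig, ablate, build_glcnet, save_checkpoint
from .synthetic import SynthConfig, generate_epochs
from .training import TrainConfig, evaluate, train_two_stage

log = logging.getLogger("glcnet")

__all__ = ["ExperimentConfig", "run_experiment", "export_features"]


@dataclasses.dataclass
class ExperimentConfig:
    """Everything one run needs; exactly one of data_path / synth."""

    data_path: str | None = None
    synth: SynthConfig | None = None
    bank: FilterBankSpec | None = None
    graph_mode: str = "pli"  # {"pli", "distance", "custom"}
    adjacency_csv: str | None = None
    model: ModelConfig | None = None  # geometry fields are filled from data
    train: TrainConfig | None = None
    split: SplitSpec | None = None
    out_dir: str = "run"
    ablations: list[str] = dataclasses.field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.data_path is None) == (self.synth is None):
            raise ConfigurationError(
                "exactly one data source required: data_path or synth")
        if self.data_path is not None and not Path(self.data_path).exists():
            raise ConfigurationError(f"data file not found: {self.data_path}")
        if self.graph_mode not in ("pli", "distance", "custom"):
            raise ConfigurationError(f"unknown graph mode {self.graph_mode!r}")
        if self.graph_mode == "custom" and self.adjacency_csv is None:
            raise ConfigurationError("custom graph mode needs adjacency_csv")


_FLAT_SCHEMA = {
    "data_path": (str, type(None)), "graph_mode": str, "adjacency_csv": (str, type(None)),
    "out_dir": str, "ablations": list, "seed": int,
}


def config_from_yaml(path: str | Path) -> ExperimentConfig:
    """Build an ExperimentConfig from a YAML file with typed validation."""
    import yaml

    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError("experiment config must be a YAML mapping")
    kwargs: dict = {}
    for key, types in _FLAT_SCHEMA.items():
        if key in raw:
            if not isinstance(raw[key], types):
                raise ConfigurationError(
                    f"config key {key!r} has type {type(raw[key]).__name__}, "
                    f"expected {types}")
            kwargs[key] = raw[key]
    for key, cls in (("synth", SynthConfig), ("train", TrainConfig),
                     ("split", SplitSpec)):
        if key in raw:
            if not isinstance(raw[key], dict):
                raise ConfigurationError(f"config section {key!r} must be a mapping")
            kwargs[key] = cls(**raw[key])
    if "model" in raw:
        if not isinstance(raw["model"], dict):
            raise ConfigurationError("config section 'model' must be a mapping")
        m = dict(raw["model"])
        if "gcn_dims" in m:
            m["gcn_dims"] = tuple(m["gcn_dims"])
        kwargs["model"] = ModelConfig(**m)
    if "bank" in raw:
        b = dict(raw["bank"])
        if "bands" in b:
            b["bands"] = [tuple(p) for p in b["bands"]]
        kwargs["bank"] = FilterBankSpec(**b)
    unknown = set(raw) - set(_FLAT_SCHEMA) - {"synth", "train", "split", "model", "bank"}
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    return ExperimentConfig(**kwargs)


def _resolve_data(config: ExperimentConfig) -> EpochSet:
    if config.data_path is not None:
        return load_epochs(config.data_path)
    return generate_epochs(config.synth)


def _resolve_adjacency(config: ExperimentConfig, train: EpochSet,
                       bank: FilterBankSpec) -> AdjacencySpec:
    if config.graph_mode == "pli":
        return compute_pli_adjacency(train, bank=bank)
    if config.graph_mode == "distance":
        return compute_distance_adjacency(train.positions)
    return adjacency_from_csv(config.adjacency_csv)


def _model_for_data(config: ExperimentConfig, data: EpochSet,
                    adjacency: AdjacencySpec, bank: FilterBankSpec,
                    removed: str | None) -> ModelConfig:
    base = config.model
    steps = 5  # fused temporal length; avg_window derived to preserve it
    avg_window = max(1, data.n_times // steps)
    kwargs = dict(
        n_channels=data.n_channels,
        n_times=data.n_times,
        n_bands=bank.n_bands,
        n_classes=data.n_classes,
        avg_window=avg_window,
        adjacency=adjacency,
    )
    if base is not None:
        d = base.to_dict()
        d.pop("adjacency_mode", None)
        d.pop("removed", None)
        d["gcn_dims"] = tuple(d["gcn_dims"])
        for k in ("n_channels", "n_times", "n_bands", "n_classes"):
            d.pop(k, None)
        d.pop("avg_window", None)
        kwargs.update(d)
    cfg = ModelConfig(**kwargs)
    return ablate(cfg, removed) if removed else cfg


def _single_run(name: str, config: ExperimentConfig, out: Path,
                train: EpochSet, val: EpochSet, test: EpochSet,
                adjacency: AdjacencySpec, bank: FilterBankSpec,
                removed: str | None) -> dict:
    run_dir = out / name
    run_dir.mkdir(parents=True, exist_ok=True)
    mcfg = _model_for_data(config, train, adjacency, bank, removed)
    model = build_glcnet(mcfg, seed=config.seed)
    log.info("run %s: %d trainable parameters", name,
             sum(model.parameter_registry().values()))
    log.debug("parameter registry: %s", model.parameter_registry())
    tcfg = config.train or TrainConfig(seed=config.seed)
    model, history = train_two_stage(model, train, val, tcfg, bank=bank)
    report = evaluate(model, test, bank=bank)
    history.to_csv(run_dir / "history.csv")
    report.to_json(run_dir / "metrics.json")
    from .losses_metrics import confusion
    x = apply_filterbank(test, bank).data
    preds = model.forward(x, mode="eval").argmax(axis=1)
    confusion(test.labels, preds, mcfg.n_classes).to_csv(run_dir / "confusion.csv")
    save_checkpoint(model, run_dir / "checkpoint.h5")
    return {
        "variant": name,
        "accuracy": report.accuracy,
        "kappa": report.kappa,
        "f1": report.f1,
        "best_val_accuracy": history.best_val_accuracy,
        "stage2_criterion_met": history.stage2_criterion_met,
    }


def run_experiment(config: ExperimentConfig) -> Path:
    """Execute the pipeline (and any ablations); returns the report dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO,
                        format="%(asctime)s %(name)s %(message)s")
    bank = config.bank or make_default_bank()
    stage = "load data"
    try:
        data = _resolve_data(config)
        stage = "split"
        split = config.split or SplitSpec(seed=config.seed)
        train, val, test = split_epochs(data, split)
        stage = "adjacency"
        adjacency = _resolve_adjacency(config, train, bank)
        stage = "train/evaluate"
        rows = [_single_run("full", config, out, train, val, test,
                            adjacency, bank, removed=None)]
        for removed in config.ablations:
            stage = f"ablation {removed}"
            rows.append(_single_run(removed, config, out, train, val, test,
                                    adjacency, bank, removed=removed))
    except Exception:
        log.exception("experiment failed at stage: %s", stage)
        raise
    pd.DataFrame(rows).to_csv(out / "comparison.csv", index=False)
    manifest = {
        "seed": config.seed,
        "split": dataclasses.asdict(split),
        "train": dataclasses.asdict(config.train or TrainConfig(seed=config.seed)),
        "bank": {"bands": [list(b) for b in bank.bands], "order": bank.order,
                 "rs_db": bank.stopband_attenuation_db,
                 "zero_phase": bank.zero_phase},
        "graph_mode": config.graph_mode,
        "data": config.data_path or dataclasses.asdict(config.synth),
        "ablations": list(config.ablations),
        "versions": _versions(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out


def _versions() -> dict[str, str]:
    import scipy

    from . import __version__

    return {
        "glcnet": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "python": platform.python_version(),
    }


def export_features(model: Model, epochs: EpochSet, layer: str = "fused",
                    bank: FilterBankSpec | None = None,
                    path: str | Path | None = None) -> pd.DataFrame:
    """Eval-mode activations of a fusion input/output as a labelled table.

    ``layer`` is one of ``fused``, ``f1``, ``f2``, ``f3``; rows are trials,
    columns the flattened feature map plus a ``label`` column.  Written as
    CSV when ``path`` is given.
    """
    bank = bank or make_default_bank()
    x = apply_filterbank(epochs, bank).data
    feats = model.branch_features(x)
    if layer not in feats:
        raise KeyError(
            f"unknown or ablated layer {layer!r}; available: {sorted(feats)}")
    flat = feats[layer].reshape(epochs.n_trials, -1)
    df = pd.DataFrame(flat, columns=[f"x{i}" for i in range(flat.shape[1])])
    df.insert(0, "label", epochs.labels)
    if path is not None:
        df.to_csv(path, index=False)
    return df
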