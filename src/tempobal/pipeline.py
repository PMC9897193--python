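"""Pipeline stages binding simulation, encoding, training and evaluation.

Each stage reads/writes conventional artifact names inside one output
directory and records a manifest entry, so every file on disk traces back to
a (config hash, seed, stage) triple. All randomness descends from the single
run seed through documented ``SeedSequence`` spawn keys:

* replicate ``r`` of class ``c``:      ``SeedSequence(seed, spawn_key=(c, r))``
* training repeat ``k``:               integer seed ``seed + k``
* fixture generation:                  ``SeedSequence(seed, spawn_key=(kind,))``
"""

from __future__ import annotations

import datetime
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .config import (
    RunConfig,
    config_hash,
    network_spec,
    sim_configs,
    train_config,
)
from .encode import EncodedDataset, encode_samples
from .errors import DependencyError
from .msio import read_ms_like, write_ms_like
from .network import NetworkSpec, TwoBranchNet, build_network
from .simulate import simulate_dataset
from .train_eval import (
    EvalReport,
    ablation_compare,
    evaluate_model,
    split_dataset,
    train_model,
)

__all__ = [
    "run_stage",
    "STAGES",
    "simulate_encoded",
    "make_splits",
    "save_checkpoint",
    "load_checkpoint",
    "write_report",
]

STAGES = ("simulate", "encode", "train", "evaluate", "ablate", "all")


# ---------------------------------------------------------------------------
# in-memory helpers (also used by the test-suite and the acceptance script)


def simulate_encoded(cfg: RunConfig, seed: Optional[int] = None) -> EncodedDataset:
    """Simulate the configured dataset and encode it in one go."""
    seed = cfg.seed if seed is None else seed
    configs = sim_configs(cfg)
    samples = simulate_dataset(configs, cfg.dataset.n_per_class, seed)
    classes = [c.name for c in cfg.dataset.classes]
    return encode_samples(samples, cfg.encoding.width, classes)


def make_splits(ds: EncodedDataset, fractions, seed: int) -> dict:
    tr, va, te = split_dataset(ds.labels, tuple(fractions), seed)
    return {"train": ds.subset(tr), "val": ds.subset(va), "test": ds.subset(te)}


# ---------------------------------------------------------------------------
# checkpoints and reports


def save_checkpoint(model: TwoBranchNet, path) -> None:
    arrays = {f"w{i}": w for i, w in enumerate(model.get_weights())}
    np.savez(
        path,
        spec=np.bytes_(model.spec.to_json().encode()),
        n_ancient_channels=model.n_ancient_channels,
        **arrays,
    )


def load_checkpoint(path) -> TwoBranchNet:
    with np.load(path, allow_pickle=False) as z:
        spec = NetworkSpec.from_json(bytes(z["spec"]).decode())
        model = build_network(spec, int(z["n_ancient_channels"]))
        weights = [z[f"w{i}"] for i in range(len(model.params()))]
    model.set_weights(weights)
    return model


def write_report(report: EvalReport, out_dir: Path, stem: str) -> list[Path]:
    """Long-format confusion TSV plus a JSON summary."""
    out_dir.mkdir(parents=True, exist_ok=True)
    tsv = out_dir / f"{stem}_confusion.tsv"
    pd.DataFrame(
        report.to_long_rows(), columns=["repeat", "true", "predicted", "count"]
    ).to_csv(tsv, sep="\t", index=False)
    js = out_dir / f"{stem}_summary.json"
    js.write_text(json.dumps(report.to_summary_dict(), indent=2, sort_keys=True) + "\n")
    return [tsv, js]


# ---------------------------------------------------------------------------
# on-disk stages


def _manifest(out_dir: Path, stage, cfg, seed, inputs, outputs, deterministic):
    def rel(p):
        p = Path(p)
        return str(p.relative_to(out_dir)) if p.is_relative_to(out_dir) else str(p)

    entry = {
        "stage": stage,
        "config_hash": config_hash(cfg),
        "seed": seed,
        "inputs": [rel(p) for p in inputs],
        "outputs": [rel(p) for p in outputs],
        "version": __version__,
        "timestamp": None
        if deterministic
        else datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    path = out_dir / "manifest.jsonl"
    with path.open("a") as fh:
        fh.write(json.dumps(entry, sort_keys=True) + "\n")


def _require(paths: list[Path], stage: str):
    missing = [p for p in paths if not p.exists()]
    if missing:
        raise DependencyError(
            f"stage {stage!r} is missing upstream artifacts: "
            + ", ".join(str(p) for p in missing)
        )


def _load_encoded(out_dir: Path, stage: str) -> EncodedDataset:
    path = out_dir / "encoded.npz"
    _require([path], stage)
    with np.load(path, allow_pickle=False) as z:
        return EncodedDataset(
            present=z["present"],
            ancient=z["ancient"],
            labels=z["labels"].astype(str),
            classes=[str(c) for c in z["classes"]],
        )


def run_stage(
    stage: str,
    cfg: RunConfig,
    out_dir,
    seed: Optional[int] = None,
    deterministic: bool = True,
) -> dict:
    """Execute one pipeline stage (or ``all``: simulate -> encode -> ablate)
    under ``out_dir``; returns a dict of the produced artifact paths."""
    if stage not in STAGES:
        raise DependencyError(f"unknown stage {stage!r}; expected one of {STAGES}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = cfg.seed if seed is None else seed
    artifacts: dict = {}

    if stage in ("simulate", "all"):
        samples = simulate_dataset(sim_configs(cfg), cfg.dataset.n_per_class, seed)
        ms_path = out_dir / "data.ms.txt"
        meta_path = out_dir / "metadata.tsv"
        write_ms_like(samples, ms_path, meta_path)
        _manifest(out_dir, "simulate", cfg, seed, [], [ms_path, meta_path], deterministic)
        artifacts.update(ms=ms_path, metadata=meta_path)

    if stage in ("encode", "all"):
        ms_path = out_dir / "data.ms.txt"
        meta_path = out_dir / "metadata.tsv"
        _require([ms_path, meta_path], "encode")
        samples = read_ms_like(ms_path, meta_path)
        classes = [c.name for c in cfg.dataset.classes]
        ds = encode_samples(samples, cfg.encoding.width, classes)
        enc_path = out_dir / "encoded.npz"
        np.savez_compressed(
            enc_path,
            present=ds.present,
            ancient=ds.ancient,
            labels=ds.labels.astype("U"),
            classes=np.array(ds.classes, dtype="U"),
        )
        index_path = out_dir / "index.tsv"
        pd.DataFrame(
            {
                "sample_id": np.arange(len(ds)),
                "label": ds.labels,
                "path": [f"encoded.npz#{i}" for i in range(len(ds))],
                "seed": seed,
            }
        ).to_csv(index_path, sep="\t", index=False)
        _manifest(
            out_dir, "encode", cfg, seed, [ms_path, meta_path],
            [enc_path, index_path], deterministic,
        )
        artifacts.update(encoded=enc_path, index=index_path)

    if stage == "train":
        ds = _load_encoded(out_dir, "train")
        data = make_splits(ds, cfg.training.fractions, seed)
        model, history = train_model(
            network_spec(cfg, seed=seed), train_config(cfg, seed), data, seed=seed
        )
        ckpt = out_dir / "checkpoint.npz"
        save_checkpoint(model, ckpt)
        hist_path = out_dir / "history.json"
        hist_path.write_text(json.dumps(history, indent=2) + "\n")
        _manifest(
            out_dir, "train", cfg, seed, [out_dir / "encoded.npz"],
            [ckpt, hist_path], deterministic,
        )
        artifacts.update(checkpoint=ckpt, history=hist_path)

    if stage == "evaluate":
        ds = _load_encoded(out_dir, "evaluate")
        ckpt = out_dir / "checkpoint.npz"
        _require([ckpt], "evaluate")
        model = load_checkpoint(ckpt)
        data = make_splits(ds, cfg.training.fractions, seed)
        cm, acc = evaluate_model(model, data["test"])
        report = EvalReport(
            mode=model.spec.mode,
            classes=list(ds.classes),
            matrices=cm[None],
            accuracies=np.array([acc]),
            seeds=[seed],
        )
        artifacts["report"] = write_report(report, out_dir, "evaluate")
        _manifest(
            out_dir, "evaluate", cfg, seed, [ckpt], artifacts["report"], deterministic
        )

    if stage in ("ablate", "all"):
        ds = _load_encoded(out_dir, "ablate")
        data = make_splits(ds, cfg.training.fractions, seed)
        result = ablation_compare(
            train_config(cfg, seed), data, network_spec(cfg, seed=seed)
        )
        outputs = []
        for mode, report in result.reports.items():
            outputs += write_report(report, out_dir, f"ablate_{mode}")
        cmp_path = out_dir / "ablation_summary.json"
        cmp_path.write_text(
            json.dumps(result.to_summary_dict(), indent=2, sort_keys=True) + "\n"
        )
        outputs.append(cmp_path)
        _manifest(
            out_dir, "ablate", cfg, seed, [out_dir / "encoded.npz"], outputs,
            deterministic,
        )
        artifacts["ablation"] = cmp_path

    return artifacts
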