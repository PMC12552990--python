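"""End-to-end orchestration: simulate -> preprocess -> DMA -> train -> evaluate -> apply.

A run is described by one YAML config (see :data:`DEFAULT_CONFIG` for the
full key set and defaults) and produces a directory of delimited-text
result tables plus ``manifest.json`` recording package version, seeds,
parameter values, input hashes and the files each stage wrote. Identical
config + seed gives identical outputs.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .annotation import load_locus_manifest, read_probe_annotation, write_probe_annotation
from .datasets import (
    CARRIER,
    MethylationDataset,
    drop_incomplete_probes,
    drop_unlabelled_samples,
    filter_probes,
    filter_samples,
    load_dataset,
    write_dataset,
)
from .dma import DifferentialMethylationModel, SignificanceConfig, call_significant
from .evaluate import apply_model, platform_degradation
from .permutation import permutation_threshold
from .predictor import (
    load_model,
    save_model,
    select_locus_probes,
    split_train_test,
    train_lasso,
)
from .simulate import (
    SimulationConfig,
    generate_cohort,
    generate_independent_cohort,
    implant_carrier_profile,
    write_ground_truth,
)

__all__ = ["RunConfig", "run_pipeline", "DEFAULT_CONFIG", "ConfigError"]

log = logging.getLogger("repeatmeth")

DEFAULT_CONFIG: dict = {
    "out_dir": "repeatmeth_run",
    "seed": 1,
    "stages": {
        "simulate": True,
        "preprocess": True,
        "dma": True,
        "train": True,
        "evaluate": True,
        "apply": True,
    },
    "inputs": {  # used when simulate is off
        "matrix": None,
        "covariates": None,
        "manifest": None,
    },
    "simulate": {
        "n_samples": 277,
        "n_carriers": 27,
        "n_background_probes": 20000,
        "n_batches": 4,
        "missing_rate": 0.0,
        "n_failing_samples": 0,
        "n_unlabelled": 0,
        "implant_profile": True,
        "validation_n_samples": 2458,
        "validation_n_carriers": 4,
    },
    "preprocess": {
        "max_missing_fraction": 0.05,
        "flags_to_drop": [
            "low_detection",
            "sex_chromosome",
            "snp_overlap",
            "cross_reactive",
            "manufacturer_flagged",
        ],
    },
    "dma": {
        "moderate": True,
        "n_permutations": 100,
        "literature_threshold": 9e-8,
    },
    "train": {
        "platform": "epicv2",
        "train_fraction": 0.7,
        "cv_folds": 10,
        "threshold": 0.5,
    },
    "evaluate": {
        "n_iterations": 100,
        "platforms": ["epicv2", "epicv1", "m450k", "m27k"],
        "comparison_test": "welch",
    },
    "apply": {"model": None, "matrix": None, "covariates": None},
}


class ConfigError(ValueError):
    """Invalid run configuration."""


def _validate_keys(given: dict, allowed: dict, path: str = "") -> None:
    for key, val in given.items():
        here = f"{path}.{key}" if path else key
        if key not in allowed:
            raise ConfigError(f"unknown config key: {here!r}")
        if isinstance(allowed[key], dict) and isinstance(val, dict):
            _validate_keys(val, allowed[key], here)


@dataclass
class RunConfig:
    """Validated pipeline configuration (defaults merged in)."""

    config: dict

    @classmethod
    def from_dict(cls, overrides: dict | None = None) -> "RunConfig":
        overrides = overrides or {}
        _validate_keys(overrides, DEFAULT_CONFIG)
        merged = copy.deepcopy(DEFAULT_CONFIG)

        def merge(dst, src):
            for k, v in src.items():
                if isinstance(v, dict) and isinstance(dst.get(k), dict):
                    merge(dst[k], v)
                else:
                    dst[k] = v

        merge(merged, overrides)
        if merged["seed"] is None:
            raise ConfigError("seed is mandatory for any stochastic stage")
        stages = merged["stages"]
        if not stages["simulate"]:
            for key in ("matrix", "covariates"):
                p = merged["inputs"][key]
                if p is None or not Path(p).exists():
                    raise ConfigError(
                        f"inputs.{key} must exist when the simulate stage is off"
                    )
        return cls(config=merged)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError("config file must contain a mapping")
        return cls.from_dict(data)

    def __getitem__(self, key):
        return self.config[key]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the enabled stages in order; returns the run manifest.

    On a stage failure the manifest (including the failure point) is still
    written before the exception propagates.
    """
    c = cfg.config
    out_dir = Path(c["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(c["seed"])
    manifest: dict = {
        "package": "repeatmeth",
        "version": __version__,
        "seed": seed,
        "parameters": copy.deepcopy(c),
        "inputs": {},
        "stages": {},
    }
    state: dict = {}

    def record(stage: str, files: dict) -> None:
        manifest["stages"][stage] = {
            "outputs": {k: str(v) for k, v in files.items()}
        }
        log.info("stage %s complete: %s", stage, list(files))

    try:
        if c["stages"]["simulate"]:
            _stage_simulate(c, seed, out_dir, state, record)
        else:
            _stage_load(c, state, manifest)
        if c["stages"]["preprocess"]:
            _stage_preprocess(c, out_dir, state, record)
        if c["stages"]["dma"]:
            _stage_dma(c, seed, out_dir, state, record)
        if c["stages"]["train"]:
            _stage_train(c, seed, out_dir, state, record)
        if c["stages"]["evaluate"]:
            _stage_evaluate(c, seed, out_dir, state, record)
        if c["stages"]["apply"]:
            _stage_apply(c, out_dir, state, record)
    except Exception as err:
        manifest["failure"] = {
            "stage": _next_unrecorded_stage(c, manifest),
            "error": str(err),
        }
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def _next_unrecorded_stage(c, manifest):
    for name, on in c["stages"].items():
        if on and name not in manifest["stages"]:
            return name
    return "unknown"


def _stage_simulate(c, seed, out_dir, state, record):
    s = c["simulate"]
    sim = SimulationConfig(
        n_samples=s["n_samples"],
        n_carriers=s["n_carriers"],
        n_background_probes=s["n_background_probes"],
        n_batches=s["n_batches"],
        missing_rate=s["missing_rate"],
        n_failing_samples=s["n_failing_samples"],
        n_unlabelled=s["n_unlabelled"],
        seed=seed,
    )
    if s["implant_profile"]:
        sim = implant_carrier_profile(sim)
    ds, ann, truth = generate_cohort(sim)
    log.info(
        "simulated %d samples x %d probes (%d carriers)",
        ds.n_samples, ds.n_probes, len(truth.carrier_ids),
    )
    vds, vtruth = generate_independent_cohort(
        SimulationConfig(
            n_samples=s["validation_n_samples"],
            n_carriers=0,
            n_background_probes=0,
            n_batches=s["n_batches"],
            seed=seed,
            affected_probes=sim.affected_probes,
        ),
        n_hidden_carriers=s["validation_n_carriers"],
    )
    paths = {f"cohort_{k}": v for k, v in write_dataset(ds, out_dir, prefix="cohort").items()}
    paths.update(
        {f"validation_{k}": v for k, v in write_dataset(vds, out_dir, prefix="validation").items()}
    )
    paths["manifest"] = out_dir / "probe_manifest.tsv"
    write_probe_annotation(ann, paths["manifest"])
    paths["ground_truth"] = out_dir / "ground_truth.tsv"
    write_ground_truth(truth, paths["ground_truth"])
    paths["validation_truth"] = out_dir / "validation_truth.tsv"
    write_ground_truth(vtruth, paths["validation_truth"])
    state.update(ds=ds, ann=ann, truth=truth, validation=vds, validation_truth=vtruth)
    record("simulate", paths)


def _stage_load(c, state, manifest):
    inputs = c["inputs"]
    state["ds"] = load_dataset(inputs["matrix"], inputs["covariates"])
    if inputs["manifest"]:
        state["ann"] = read_probe_annotation(inputs["manifest"])
    else:
        state["ann"] = load_locus_manifest()
    for key in ("matrix", "covariates", "manifest"):
        if inputs[key]:
            manifest["inputs"][key] = {
                "path": str(inputs[key]),
                "sha256": _sha256(inputs[key]),
            }


def _stage_preprocess(c, out_dir, state, record):
    p = c["preprocess"]
    ds = state["ds"]
    ds, sample_report = filter_samples(ds, p["max_missing_fraction"])
    log.info("sample filter: removed %d, %d remain", sample_report.n_removed, ds.n_samples)
    ds, probe_report = filter_probes(ds, state["ann"], set(p["flags_to_drop"]))
    log.info("probe filter: removed %d, %d remain", probe_report.n_removed, ds.n_probes)
    if ds.carrier is not None:
        ds, unlabelled = drop_unlabelled_samples(ds)
        log.info("dropped %d unlabelled samples, %d remain", len(unlabelled), ds.n_samples)
    ds, incomplete = drop_incomplete_probes(ds)
    log.info("dropped %d incomplete probes, %d remain", len(incomplete), ds.n_probes)
    state["ds"] = ds
    report = out_dir / "preprocess_report.json"
    report.write_text(
        json.dumps(
            {
                "samples_removed_call_rate": sample_report.removed.to_dict(),
                "probes_removed_by_flag": probe_report.counts_by_flag,
                "unlabelled_samples_removed": len(unlabelled) if ds.carrier is not None else 0,
                "incomplete_probes_removed": len(incomplete),
                "final_samples": ds.n_samples,
                "final_probes": ds.n_probes,
            },
            indent=2,
        )
    )
    record("preprocess", {"report": report})


def _stage_dma(c, seed, out_dir, state, record):
    d = c["dma"]
    ds = state["ds"]
    res = DifferentialMethylationModel(ds).fit(moderate=d["moderate"])
    perm = permutation_threshold(
        ds, n_permutations=d["n_permutations"], seed=seed, moderate=d["moderate"]
    )
    sig = SignificanceConfig(
        literature_threshold=d["literature_threshold"],
        permutation_threshold=perm.threshold,
    )
    hits = call_significant(res, sig)
    log.info(
        "DMA: lambda_gc=%.3f, permutation threshold=%.3g, %d significant probes",
        res.lambda_gc, perm.threshold, len(hits),
    )
    paths = {
        "dma_table": out_dir / "dma_results.tsv",
        "significant": out_dir / "dma_significant.tsv",
        "permutation": out_dir / "permutation_report.tsv",
    }
    res.table.to_csv(paths["dma_table"], sep="\t")
    hits.to_csv(paths["significant"], sep="\t")
    pd.DataFrame(
        {"permutation": range(perm.n_permutations), "min_p": perm.min_p_per_perm}
    ).to_csv(paths["permutation"], sep="\t", index=False)
    state.update(dma=res, perm=perm, significant=hits)
    record("dma", paths)


def _stage_train(c, seed, out_dir, state, record):
    t = c["train"]
    ds = state["ds"]
    probes = select_locus_probes(state["ann"], platform=t["platform"])
    probes = [p for p in probes if p in ds.m_values.columns]
    train, test = split_train_test(ds, train_fraction=t["train_fraction"], seed=seed)
    model = train_lasso(train, probes, cv_folds=t["cv_folds"], seed=seed)
    from .evaluate import SplitMetrics
    from .predictor import predict_carriers

    calls = predict_carriers(model, test, threshold=t["threshold"])
    m = SplitMetrics.from_labels(
        test.carrier_mask(), (calls["label"] == CARRIER).to_numpy()
    )
    log.info(
        "single-split model: %d/%d features selected, test accuracy %.3f",
        len(model.selected_probes), len(model.probe_ids), m.accuracy,
    )
    paths = {"model": out_dir / "predictor.model", "single_split": out_dir / "single_split_metrics.json"}
    save_model(model, paths["model"])
    paths["single_split"].write_text(
        json.dumps(
            {"tp": m.tp, "fp": m.fp, "tn": m.tn, "fn": m.fn, "accuracy": m.accuracy},
            indent=2,
        )
    )
    state["model"] = model
    record("train", paths)


def _stage_evaluate(c, seed, out_dir, state, record):
    e = c["evaluate"]
    results, comparison = platform_degradation(
        state["ds"],
        state["ann"],
        n_iterations=e["n_iterations"],
        root_seed=seed,
        platforms=tuple(e["platforms"]),
        test=e["comparison_test"],
        threshold=c["train"]["threshold"],
        train_fraction=c["train"]["train_fraction"],
        cv_folds=c["train"]["cv_folds"],
    )
    frames = [r.to_frame().assign(platform=p) for p, r in results.items()]
    paths = {
        "iterations": out_dir / "evaluation_iterations.tsv",
        "summary": out_dir / "evaluation_summary.tsv",
        "comparison": out_dir / "platform_comparison.tsv",
    }
    pd.concat(frames, ignore_index=True).to_csv(paths["iterations"], sep="\t", index=False)
    pd.DataFrame([r.summary() for r in results.values()]).to_csv(
        paths["summary"], sep="\t", index=False
    )
    comparison.table.to_csv(paths["comparison"], sep="\t", index=False)
    for p, r in results.items():
        s = r.summary()
        log.info(
            "platform %s (%d probes): accuracy %.3f, type1 %.4f, type2 %.3f",
            p, r.n_probes, s["accuracy_mean"], s["type1_mean"], s["type2_mean"],
        )
    state["evaluation"] = results
    record("evaluate", paths)


def _stage_apply(c, out_dir, state, record):
    a = c["apply"]
    model = load_model(a["model"]) if a["model"] else state.get("model")
    if model is None:
        raise ValueError("apply stage needs a trained model (stage or apply.model)")
    if a["matrix"]:
        target = load_dataset(a["matrix"], a["covariates"])
    else:
        target = state.get("validation")
        if target is None:
            raise ValueError("apply stage needs apply.matrix or a simulated validation cohort")
    calls = apply_model(model, target)
    log.info("apply: %s", calls.summary())
    paths = {"calls": out_dir / "carrier_calls.tsv"}
    calls.calls.to_csv(paths["calls"], sep="\t")
    state["calls"] = calls
    record("apply", paths)
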