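"""End-to-end orchestration: simulate -> build table -> invert -> classify.

A run is described by one YAML-serializable :class:`RunConfig`; every source
of randomness derives from its single root seed (stage streams are spawned
deterministically), so re-running an identical config reproduces identical
artifacts.  Each run emits, into its output directory:

    lsps.h5       simulated labelled LSPs (+ ground truth)
    features.csv  inverted biophysical properties per cell
    report.json   classification reports per requested task
    manifest.json config hash, stage timings, artifact list
    run.log       structured per-stage log
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as sio
from .classify import ClassifierConfig, cross_validate
from .lookup import DEFAULT_GRID, GridSpec, build_lookup, extract_features_matrix
from .optics import OpticalConfig
from .population import (
    LSPSet,
    NoiseModel,
    PhenotypeSpec,
    default_phenotype_specs,
    simulate_dataset,
)

__all__ = ["RunConfig", "run_pipeline", "make_fixtures", "TASKS"]

logger = logging.getLogger(__name__)

# Classification tasks named after the study's three experiments.
TASKS = {
    "m1m2": (("M1", "M2"), ClassifierConfig(kind="quadratic_svm")),
    "m0m1m2": (("M0", "M1", "M2"), ClassifierConfig(kind="cosine_knn")),
    "mono-m0": (("Mono", "M0"), ClassifierConfig(kind="quadratic_svm")),
}


@dataclass
class RunConfig:
    """Complete description of a pipeline run."""

    seed: int
    outdir: str
    optics: OpticalConfig = field(default_factory=OpticalConfig)
    grid: GridSpec = field(default_factory=GridSpec)
    noise: NoiseModel = field(default_factory=NoiseModel)
    phenotypes: dict[str, PhenotypeSpec] = field(default_factory=default_phenotype_specs)
    tasks: list[str] = field(default_factory=lambda: ["m1m2", "m0m1m2", "mono-m0"])
    classifier_overrides: dict[str, ClassifierConfig] = field(default_factory=dict)
    lut_cache: str | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a run must carry an explicit seed")
        unknown = [t for t in self.tasks if t not in TASKS]
        if unknown:
            raise ValueError(f"unknown tasks {unknown}; valid: {sorted(TASKS)}")

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "outdir": self.outdir,
            "optics": self.optics.to_dict(),
            "grid": self.grid.to_dict(),
            "noise": self.noise.to_dict(),
            "phenotypes": {k: v.to_dict() for k, v in self.phenotypes.items()},
            "tasks": list(self.tasks),
            "classifier_overrides": {
                k: v.__dict__ for k, v in self.classifier_overrides.items()
            },
        }

    def config_hash(self) -> str:
        payload = {k: v for k, v in self.to_dict().items() if k != "outdir"}
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as f:
            raw = yaml.safe_load(f)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        if "seed" not in raw:
            raise ValueError("config must specify a seed")
        kw = dict(seed=raw["seed"], outdir=raw.get("outdir", "run_output"))
        if "optics" in raw:
            kw["optics"] = OpticalConfig(**raw["optics"])
        if "grid" in raw:
            kw["grid"] = GridSpec.from_dict(raw["grid"])
        if "noise" in raw:
            kw["noise"] = NoiseModel(**raw["noise"])
        if "phenotypes" in raw:
            kw["phenotypes"] = {
                k: PhenotypeSpec(**v) for k, v in raw["phenotypes"].items()
            }
        if "tasks" in raw:
            kw["tasks"] = list(raw["tasks"])
        if "classifier_overrides" in raw:
            kw["classifier_overrides"] = {
                k: ClassifierConfig(**v) for k, v in raw["classifier_overrides"].items()
            }
        if "lut_cache" in raw:
            kw["lut_cache"] = raw["lut_cache"]
        return cls(**kw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(self.to_dict(), f, sort_keys=True)


def _derive_seed(root: int, stage: str) -> int:
    h = hashlib.sha256(f"{root}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages; returns (and writes) the run manifest.

    Any stage failure aborts with the stage named; inputs are never mutated.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    manifest: dict = {
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "stages": {},
        "artifacts": [],
    }
    stage = "simulate"
    try:
        t0 = time.perf_counter()
        lsps, truth = simulate_dataset(
            cfg.phenotypes, cfg.optics, cfg.noise,
            seed=_derive_seed(cfg.seed, "simulate"), grid=cfg.grid,
        )
        sio.write_lsp_set_h5(lsps, outdir / "lsps.h5", truth=truth)
        truth.to_csv(outdir / "truth.csv", index=False)
        manifest["stages"][stage] = {"seconds": round(time.perf_counter() - t0, 3), "cells": len(lsps)}
        manifest["artifacts"] += ["lsps.h5", "truth.csv"]
        logger.info("simulate: %d cells", len(lsps))

        stage = "build-lut"
        t0 = time.perf_counter()
        table = build_lookup(cfg.grid, cfg.optics, cache_path=cfg.lut_cache)
        manifest["stages"][stage] = {
            "seconds": round(time.perf_counter() - t0, 3),
            "rows": table.row_count,
            "lut_hash": table.config_hash(),
        }
        logger.info("build-lut: %d rows", table.row_count)

        stage = "invert"
        t0 = time.perf_counter()
        features = extract_features_matrix(lsps.intensities, lsps.labels, table)
        sio.write_feature_table(features, outdir / "features.csv")
        manifest["stages"][stage] = {
            "seconds": round(time.perf_counter() - t0, 3),
            "flagged": int(features["flagged"].sum()),
        }
        manifest["artifacts"].append("features.csv")
        logger.info("invert: %d rows, %d flagged", len(features), features["flagged"].sum())

        stage = "classify"
        t0 = time.perf_counter()
        reports = {}
        for task in cfg.tasks:
            labels, default_cfg = TASKS[task]
            ccfg = cfg.classifier_overrides.get(task, default_cfg)
            ccfg = type(ccfg)(**{**ccfg.__dict__, "seed": _derive_seed(cfg.seed, f"cv:{task}")})
            subset = features[features["label"].isin(labels)].reset_index(drop=True)
            reports[task] = cross_validate(subset, ccfg).to_dict()
        with open(outdir / "report.json", "w") as f:
            json.dump(reports, f, indent=2, sort_keys=True)
        manifest["stages"][stage] = {"seconds": round(time.perf_counter() - t0, 3)}
        manifest["artifacts"].append("report.json")
        for task, rep in reports.items():
            logger.info("classify[%s]: mean accuracy %.1f%%", task, rep["mean_accuracy"])
    except Exception as exc:
        manifest["failed_stage"] = stage
        with open(outdir / "manifest.json", "w") as f:
            json.dump(manifest, f, indent=2, sort_keys=True, default=str)
        logger.removeHandler(handler)
        handler.close()
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(outdir / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=2, sort_keys=True, default=str)
    manifest["artifacts"].append("manifest.json")
    logger.removeHandler(handler)
    handler.close()
    return manifest


# ---------------------------------------------------------------------------
# Test fixtures


def toy_grid() -> GridSpec:
    """A 240-row grid spanning the same ranges as the default grid, coarse
    enough for exhaustive brute-force checks."""
    from .lookup import AxisSpec

    return GridSpec(
        diameter=AxisSpec(8.0, 16.0, 2.0),      # 5
        nc_ratio=AxisSpec(0.75, 0.90, 0.05),    # 4
        ri_nucleus=AxisSpec(1.38, 1.44, 0.02),  # 4
        ri_cytoplasm=AxisSpec(1.34, 1.40, 0.03),  # 3
    )


def make_fixtures(seed: int = 0, outdir: str | Path = "fixtures") -> dict:
    """Deterministic small bundle for tests: toy-grid LUT, a 40-cell LSP set
    (10 per phenotype) and its ground truth.  No network access, ever."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    grid = toy_grid()
    optics = OpticalConfig()
    table = build_lookup(grid, optics, cache_path=outdir / "toy_lut.h5")
    specs = default_phenotype_specs()
    lsps, truth = simulate_dataset(
        specs, optics, NoiseModel(), seed=_derive_seed(seed, "fixtures"),
        n_overrides={k: 10 for k in specs}, grid=DEFAULT_GRID,
    )
    sio.write_lsp_set_h5(lsps, outdir / "toy_lsps.h5", truth=truth)
    truth.to_csv(outdir / "toy_truth.csv", index=False)
    checksum = hashlib.sha256(
        np.ascontiguousarray(lsps.intensities).tobytes()
    ).hexdigest()[:16]
    return {
        "lut": str(outdir / "toy_lut.h5"),
        "lsps": str(outdir / "toy_lsps.h5"),
        "truth": str(outdir / "toy_truth.csv"),
        "checksum": checksum,
        "rows": table.row_count,
    }
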