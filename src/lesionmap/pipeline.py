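"""End-to-end orchestration: simulate -> segment -> features -> table1 ->
fit -> report, with a run manifest for reproducibility checks."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cohort_stats import build_table1
from .features import build_feature_table
from .modeling import ModelSpec, compare_models, region_importance, repeated_cv
from .segmentation import SegmentationParams
from .simulate import SimConfig, generate_cohort, planted_effect_config, write_cohort

log = logging.getLogger("lesionmap")


class StageError(RuntimeError):
    def __init__(self, stage: str, err: Exception):
        super().__init__(f"stage {stage!r} failed: {err}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    out_dir: Path
    cohort_dir: Path | None = None  # None -> simulate into out_dir/cohort
    sim: SimConfig | None = None
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    specs: list[ModelSpec] = field(default_factory=list)
    folds: int = 10
    repeats: int = 20
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = None
        if "sim" in raw:
            sim_raw = dict(raw["sim"])
            planted = sim_raw.pop("planted_effects", None)
            for key in ("grid_shape", "voxel_size"):
                if key in sim_raw:
                    sim_raw[key] = tuple(sim_raw[key])
            for key in ("effect_regions", "betas_region"):
                if key in sim_raw:
                    sim_raw[key] = tuple(sim_raw[key])
            if planted:
                sim = planted_effect_config(**planted, **sim_raw)
            else:
                sim = SimConfig(**sim_raw)
        seg = SegmentationParams(**raw.get("segmentation", {}))
        specs = [ModelSpec(**s) for s in raw.get("models", [])]
        return cls(
            out_dir=Path(raw["out_dir"]),
            cohort_dir=Path(raw["cohort_dir"]) if raw.get("cohort_dir") else None,
            sim=sim,
            segmentation=seg,
            specs=specs,
            folds=int(raw.get("folds", 10)),
            repeats=int(raw.get("repeats", 20)),
            seed=int(raw.get("seed", 0)),
        )

    def config_hash(self) -> str:
        blob = json.dumps(
            {
                "sim": None if self.sim is None else {
                    k: getattr(self.sim, k) for k in self.sim.__dataclass_fields__
                },
                "segmentation": {
                    k: getattr(self.segmentation, k)
                    for k in self.segmentation.__dataclass_fields__
                },
                "models": [
                    {k: getattr(s, k) for k in s.__dataclass_fields__} for s in self.specs
                ],
                "folds": self.folds,
                "repeats": self.repeats,
                "seed": self.seed,
            },
            sort_keys=True,
            default=list,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow and write a run manifest.

    Stages run in order; any failure aborts with a stage-named error and the
    outputs produced so far are retained on disk. The manifest records the
    config hash, per-output checksums, software version and timings; with an
    identical config and inputs the deterministic stages reproduce identical
    checksums.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
        "checksums": {},
    }
    provenance = f"lesionmap {__version__} | config {manifest['config_hash']} | seed {config.seed}"

    def stage(name):
        def deco(fn):
            t0 = time.time()
            log.info("stage %s ...", name)
            try:
                fn()
            except Exception as err:
                manifest["stages"][name] = {"status": "failed", "error": str(err)}
                (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
                raise StageError(name, err) from err
            manifest["stages"][name] = {
                "status": "ok",
                "seconds": round(time.time() - t0, 2),
            }

        return deco

    cohort_dir = config.cohort_dir or out / "cohort"

    if config.sim is not None:
        @stage("simulate")
        def _simulate():
            cohort = generate_cohort(config.sim)
            write_cohort(cohort, cohort_dir)

    features_csv = out / "features.csv"

    @stage("features")
    def _features():
        from .io import write_table

        if not (Path(cohort_dir) / "clinical.csv").exists():
            raise FileNotFoundError(f"clinical.csv missing from {cohort_dir}")
        table = build_feature_table(cohort_dir, config.segmentation)
        write_table(table, features_csv, provenance)

    @stage("table1")
    def _table1():
        from .io import read_table, write_table

        table = read_table(features_csv)
        write_table(build_table1(table), out / "table1.csv", provenance)

    results = {}

    @stage("fit")
    def _fit():
        from .io import read_table, write_table

        table = read_table(features_csv)
        for spec in config.specs:
            cv = repeated_cv(spec, table, config.folds, config.repeats, config.seed)
            results[spec.name] = cv
            prefix = spec.name.lower().replace("-", "_")
            write_table(cv.per_repeat(), out / f"{prefix}_repeats.csv", provenance)
            write_table(
                cv.summary().reset_index(names="metric"),
                out / f"{prefix}_summary.csv",
                provenance,
            )
            if spec.selector != "none":
                write_table(
                    region_importance(cv), out / f"{prefix}_selection.csv", provenance
                )

    @stage("report")
    def _report():
        from .io import write_table

        rows = []
        for name, cv in results.items():
            s = cv.summary()
            rows.append(
                {"model": name}
                | {f"{m}_mean": s.loc[m, "mean"] for m in s.index}
                | {f"{m}_sd": s.loc[m, "sd"] for m in s.index}
            )
        if rows:
            write_table(pd.DataFrame(rows), out / "report.csv", provenance)
        names = list(results)
        comps = []
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                p = compare_models(results[names[i]], results[names[j]])
                comps.append({"a": names[i], "b": names[j], **p})
        if comps:
            write_table(pd.DataFrame(comps), out / "model_comparisons.csv", provenance)

    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest["checksums"][str(path.relative_to(out))] = _sha256(path)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
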