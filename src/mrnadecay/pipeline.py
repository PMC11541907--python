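"""End-to-end orchestration: simulate -> count -> fit -> featurize -> train -> sweep.

A run is driven by a single config (YAML-loadable dataclass); every
stochastic stage receives a seed derived deterministically from the root
seed and the stage name, so a rerun with the same config reproduces
identical artifacts. Each stage writes TSV/JSON artifacts into the run
directory and the manifest records config hash, seeds, and row counts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from mrnadecay._errors import ConfigurationError, DataError, ValidationError
from mrnadecay import barcodes as bc
from mrnadecay import kinetics as kin
from mrnadecay import synthetic_data as sd
from mrnadecay.features import build_schema, featurize_library, providers_for_library
from mrnadecay.model import Dataset, ModelBundle, split_by_group, train_bundle

logger = logging.getLogger("mrnadecay")


@dataclass
class RunConfig:
    outdir: str = "run"
    seed: int = 0
    library_scale: float = 0.3
    library_config: dict | None = None  # overrides the default group mix
    depth_per_variant: int = 1000
    error_rate: float = 0.0
    emit_fastq: bool = False
    min_reads: int = 100
    r2_threshold: float = 0.75
    timepoints: tuple[float, ...] = kin.DEFAULT_TIMEPOINTS
    train_fraction: float = 0.8
    hyperparams: dict = field(default_factory=dict)
    truth_params: dict = field(default_factory=dict)
    stages: tuple[str, ...] = ("simulate", "count", "fit", "featurize", "train", "sweep")

    def __post_init__(self):
        if self.min_reads <= 0 or not 0 < self.r2_threshold < 1:
            raise ConfigurationError("QC thresholds must be positive (r2 in (0,1))")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if "timepoints" in raw:
            raw["timepoints"] = tuple(raw["timepoints"])
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def derive_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: sha256(root_seed || stage) mod 2^31."""
    digest = hashlib.sha256(f"{root_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def build_dataset(library, table: kin.CountTable, fits: pd.DataFrame,
                  features: pd.DataFrame, schema, split_seed: int = 0,
                  train_fraction: float = 0.8) -> Dataset:
    """Assemble the modeling dataset from pipeline artifacts (QC-passing rows)."""
    idx = fits.index.intersection(features.index)
    outcomes = kin.level_outcomes(table).loc[idx]
    outcomes["k"] = fits.loc[idx, "k"]
    groups = pd.Series({v.variant_id: v.design_group for v in library}).loc[idx]
    ds = Dataset(X=features.loc[idx], outcomes=outcomes, groups=groups, schema=schema)
    ds.split = split_by_group(ds.groups, train_fraction=train_fraction, seed=split_seed)
    return ds


def run_pipeline(config: RunConfig) -> dict:
    """Execute the toggled stages; returns the manifest dict."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
    }
    t_start = time.time()
    state: dict = {}

    def finish_stage(name: str, rows: int) -> None:
        manifest["stages"][name] = {
            "rows": rows,
            "seed": derive_seed(config.seed, name),
            "elapsed_s": round(time.time() - t_start, 2),
        }
        logger.info("stage %s done (%d rows)", name, rows)

    try:
        if "simulate" in config.stages:
            lib = sd.generate_design_library(
                config.library_config or sd.default_library_config(config.library_scale),
                seed=derive_seed(config.seed, "library"),
            )
            lib, spike_bc = sd.attach_barcodes(lib, seed=derive_seed(config.seed, "barcodes"))
            truth = sd.generate_truth(
                lib, sd.TruthParams(**config.truth_params), seed=derive_seed(config.seed, "truth")
            )
            table = sd.simulate_counts(
                truth,
                depth=config.depth_per_variant * len(lib),
                timepoints=config.timepoints,
                seed=derive_seed(config.seed, "simulate"),
            )
            sd.library_to_frame(lib).to_csv(outdir / "library.tsv", sep="\t", index=False)
            sd.truth_to_frame(truth).to_csv(outdir / "truth.tsv", sep="\t", index=False)
            table.to_tsv(outdir / "counts.tsv")
            state.update(library=lib, spike_barcode=spike_bc, truth=truth, table=table)
            finish_stage("simulate", len(lib))

            if config.emit_fastq and "count" in config.stages:
                bmap = {v.variant_id: v.barcode for v in lib}
                bmap[kin.SPIKEIN_ID] = spike_bc
                fastq_dir = outdir / "fastq"
                paths = sd.emit_reads(
                    table, bmap, fastq_dir, error_rate=config.error_rate,
                    seed=derive_seed(config.seed, "reads"),
                )
                index = bc.build_index(bmap)
                locator = bc.BarcodeLocator(
                    length=15, anchor5=sd.READ_ANCHOR5, anchor3=sd.READ_ANCHOR3
                )
                counted, report = bc.count_samples(paths, index, locator)
                counted = counted.reindex(table.df.index).fillna(0).astype(int)
                counted.loc[kin.SPIKEIN_ID, "dna_t0"] = 0
                table = kin.CountTable(counted, config.timepoints)
                state["table"] = table
                bc.write_report(report, outdir / "mapping_report.json")
                table.to_tsv(outdir / "counts.tsv")
                finish_stage("count", len(table.variant_ids))

        if "fit" in config.stages:
            table = state["table"]
            norm = kin.normalize(table)
            fits = kin.fit_decay_table(norm, config.timepoints, config.r2_threshold)
            kept, qc = kin.apply_qc(fits, table, config.min_reads, config.r2_threshold)
            fits.to_csv(outdir / "fits_all.tsv", sep="\t", index_label="variant_id")
            kept.to_csv(outdir / "fits.tsv", sep="\t", index_label="variant_id")
            (outdir / "qc.json").write_text(json.dumps(qc, indent=2))
            state["fits"] = kept
            finish_stage("fit", len(kept))

        if "featurize" in config.stages:
            lib = state["library"]
            schema = build_schema()
            providers = providers_for_library(lib)
            X = featurize_library(lib, providers, schema)
            X.to_csv(outdir / "features.tsv", sep="\t", index_label="variant_id")
            (outdir / "schema.json").write_text(json.dumps(schema.to_json_dict(), indent=2))
            state.update(features=X, schema=schema)
            finish_stage("featurize", len(X))

        if "train" in config.stages:
            ds = build_dataset(
                state["library"], state["table"], state["fits"], state["features"],
                state["schema"], split_seed=derive_seed(config.seed, "split"),
                train_fraction=config.train_fraction,
            )
            bundle = train_bundle(ds, config.hyperparams, seed=derive_seed(config.seed, "train"))
            bundle.save(outdir / "model")
            (outdir / "metrics.json").write_text(json.dumps(bundle.metrics, indent=2))
            state.update(dataset=ds, bundle=bundle)
            finish_stage("train", len(ds.X))

        if "sweep" in config.stages:
            from mrnadecay import rules

            ds, bundle, schema = state["dataset"], state["bundle"], state["schema"]
            baseline = rules.baseline_from_features(ds.X, ds.outcomes["k"], schema)
            rpph = rules.sweep_rpph(baseline, bundle, schema)
            rpph.to_csv(outdir / "sweep_rpph.tsv", sep="\t", index=False)
            tir = rules.sweep_scalar(
                baseline, bundle, schema, "tir", list(np.geomspace(10, 1e6, 40))
            )
            tir.frame().to_csv(outdir / "sweep_tir.tsv", sep="\t", index=False)
            (outdir / "sweep_summary.json").write_text(
                json.dumps(
                    {
                        "rpph_top10": rpph.head(10).to_dict("records"),
                        "rpph_bottom10": rpph.tail(10).to_dict("records"),
                        "tir_plateau_onset_au": tir.plateau_onset,
                    },
                    indent=2,
                )
            )
            finish_stage("sweep", len(rpph))
    except KeyError as exc:
        raise DataError(f"stage input missing: {exc}; enable the producing stage") from exc

    manifest["elapsed_s"] = round(time.time() - t_start, 2)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


DEFAULT_COLUMN_MAPPING = {
    "variant_id": "variant_id",
    "dna_t0": "dna_t0",
    "rna_t0": "rna_t0",
    "rna_t2": "rna_t2",
    "rna_t4": "rna_t4",
    "rna_t8": "rna_t8",
    "rna_t16": "rna_t16",
}


def load_external_counts(
    counts_path: str | Path,
    column_mapping: Mapping[str, str] | None = None,
    library_path: str | Path | None = None,
    timepoints=kin.DEFAULT_TIMEPOINTS,
    spikein_id: str = kin.SPIKEIN_ID,
    sep: str = "\t",
) -> tuple[kin.CountTable, pd.DataFrame | None]:
    """Load a deposited barcode-count table through the CountTable interface.

    ``column_mapping`` maps canonical column names (dna_t0, rna_t0, ...) to
    the file's actual headers. Missing columns raise a schema error; the
    spike-in row must be present (it is renamed to the reserved id).
    """
    mapping = dict(DEFAULT_COLUMN_MAPPING, **(column_mapping or {}))
    raw = pd.read_csv(counts_path, sep=sep)
    missing = [src for src in mapping.values() if src not in raw.columns]
    if missing:
        raise ValidationError(f"external counts missing columns: {missing}")
    df = raw.rename(columns={src: dst for dst, src in mapping.items()})
    df = df.set_index("variant_id")
    if spikein_id != kin.SPIKEIN_ID:
        df = df.rename(index={spikein_id: kin.SPIKEIN_ID})
    if kin.SPIKEIN_ID not in df.index:
        raise ValidationError(f"external counts missing spike-in row {spikein_id!r}")
    table = kin.CountTable(df, timepoints)
    library = pd.read_csv(library_path, sep=sep) if library_path else None
    return table, library
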