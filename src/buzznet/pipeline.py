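"""End-to-end orchestration: simulate/ingest -> efficacy -> currencies ->
metrics -> null models -> species tables -> comparison report.

Every run writes its artifacts plus a manifest carrying the package
version, the config hash, the master seed and per-stage seeds (derived
deterministically from the master seed and the stage name) and a digest of
every artifact, so reruns with the same config reproduce every output
byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import zlib
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .compare import currency_report, report_to_json
from .currencies import build_all_currencies
from .data_model import (
    InteractionMatrix,
    aggregate_counts,
    read_group_map,
    read_references,
    read_single_visits,
    read_visits,
    write_group_map,
    write_references,
    write_single_visits,
    write_visits,
)
from .efficacy import ClampDiagnostics, single_visit_efficacies
from .metrics import find_modules, h2prime, modularity_qw, nodf, weighted_generality
from .nulls import null_test
from .species import species_table
from .synthetic import SyntheticConfig, default_config, generate

STAGES = ("simulate", "efficacy", "networks", "metrics", "nulls", "species", "compare")


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    return (int(master_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31 - 1)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


DEFAULT_CONFIG: dict = {
    "seed": 0,
    "simulate": True,
    "total_visits": 1838,
    "imputation": "group_plant_mean",
    "h2_mode": "continuous",
    "cv_threshold": 0.2,
    "null_runs": 1000,
    "null_restarts": 5,
    "modularity_restarts": 20,
    "degree_mode": "binary",
    "run_nulls": True,
    "inputs": {},
}


def load_config(source) -> dict:
    if isinstance(source, (str, Path)):
        with open(source) as handle:
            user = yaml.safe_load(handle) or {}
    else:
        user = dict(source or {})
    config = dict(DEFAULT_CONFIG)
    config.update(user)
    return config


def run_pipeline(config, out_dir: str | Path) -> dict:
    """Run the whole analysis; returns the manifest dict.

    ``config`` is a YAML path or a mapping; see ``DEFAULT_CONFIG`` for the
    recognized keys. With ``simulate: true`` the synthetic community
    generator produces the four input tables; otherwise ``inputs`` must
    name the visits/single_visits/references/groups CSV files.
    """
    config = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    master_seed = int(config["seed"])
    config_blob = json.dumps(config, sort_keys=True, default=str)
    artifacts: dict[str, str] = {}
    completed: list[str] = []

    def save_df(frame: pd.DataFrame, name: str) -> None:
        path = out / name
        frame.to_csv(path, index=False, float_format="%.12g")
        artifacts[name] = _sha256(path)

    def save_json(obj, name: str) -> None:
        path = out / name
        path.write_text(json.dumps(obj, sort_keys=True, indent=2) + "\n")
        artifacts[name] = _sha256(path)

    # --- stage: simulate / ingest -----------------------------------------
    stage = "simulate"
    try:
        if config.get("simulate", True):
            cfg = default_config(
                total_visits=float(config.get("total_visits", 1838)),
                seed=stage_seed(master_seed, stage),
            )
            tables = generate(cfg)
            visits, single_visits = tables.visits, tables.single_visits
            references, group_map = tables.references, tables.group_map
            plant_labels, bee_labels = tables.plant_labels, tables.bee_labels
            write_visits(visits, out / "visits.csv")
            write_single_visits(single_visits, out / "single_visits.csv")
            write_references(references, out / "references.csv")
            write_group_map(group_map, out / "groups.csv")
            for name in ("visits.csv", "single_visits.csv", "references.csv", "groups.csv"):
                artifacts[name] = _sha256(out / name)
        else:
            inputs = config.get("inputs", {})
            for key in ("visits", "single_visits", "references", "groups"):
                if key not in inputs:
                    raise PipelineError(stage, f"missing input table {key!r}")
            visits = read_visits(inputs["visits"])
            single_visits = read_single_visits(inputs["single_visits"])
            references = read_references(inputs["references"])
            group_map = read_group_map(inputs["groups"])
            plant_labels = sorted(
                {v.plant_species for v in visits}
                | {s.plant_species for s in single_visits}
            )
            bee_labels = sorted(group_map)
        completed.append(stage)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # --- stage: efficacy ---------------------------------------------------
    stage = "efficacy"
    try:
        diagnostics = ClampDiagnostics()
        efficacies = single_visit_efficacies(
            single_visits,
            references,
            cv_threshold=float(config["cv_threshold"]),
            diagnostics=diagnostics,
        )
        save_df(
            pd.DataFrame([dataclasses.asdict(e) for e in efficacies]),
            "efficacy.csv",
        )
        save_json(
            {
                "removal_clamped": diagnostics.removal_clamped,
                "deposition_clamped": diagnostics.deposition_clamped,
            },
            "efficacy_diagnostics.json",
        )
        completed.append(stage)
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # --- stage: networks ---------------------------------------------------
    stage = "networks"
    try:
        vn = aggregate_counts(visits, plant_labels, bee_labels)
        if not efficacies and config["imputation"] == "zero":
            raise PipelineError(stage, "no efficacy data and imputation disabled")
        matrices, imputation_reports = build_all_currencies(
            vn, efficacies, group_map, imputation=str(config["imputation"])
        )
        for name, matrix in matrices.items():
            matrix.to_csv(out / f"network_{name}.csv")
            artifacts[f"network_{name}.csv"] = _sha256(out / f"network_{name}.csv")
        save_json(
            {k: dataclasses.asdict(v) for k, v in imputation_reports.items()},
            "imputation_report.json",
        )
        completed.append(stage)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # --- stage: metrics ----------------------------------------------------
    stage = "metrics"
    try:
        partitions = {}
        metric_reports = {}
        trimmed = {}
        for name, matrix in matrices.items():
            sub, dropped = matrix.drop_empty()
            trimmed[name] = sub
            partition = find_modules(
                sub,
                n_restarts=int(config["modularity_restarts"]),
                seed=stage_seed(master_seed, f"{stage}:{name}"),
            )
            partitions[name] = partition
            h2 = h2prime(sub, mode=str(config["h2_mode"]))
            metric_reports[name] = {
                "currency": name,
                "h2_prime": h2.h2_prime,
                "h2": h2.h2,
                "h2_max": h2.h2_max,
                "h2_min": h2.h2_min,
                "h2_mode": h2.mode,
                "nodf": nodf(sub),
                "q_w": partition.qw,
                "n_modules": partition.n_modules,
                "modularity_restarts": partition.restarts_used,
                "modularity_seed": partition.seed,
                "generality_plants": weighted_generality(sub, "plants"),
                "generality_bees": weighted_generality(sub, "bees"),
                "dropped": dropped,
            }
        save_json(metric_reports, "metrics.json")
        completed.append(stage)
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # --- stage: nulls ------------------------------------------------------
    stage = "nulls"
    null_reports: dict[str, dict[str, dict]] = {}
    if config.get("run_nulls", True):
        try:
            runs = int(config["null_runs"])
            for name, sub in trimmed.items():
                seed = stage_seed(master_seed, f"{stage}:{name}")
                h2_mode = str(config["h2_mode"])
                tests = {
                    "h2_prime": lambda a: h2prime(a, mode=h2_mode).h2_prime,
                    "nodf": nodf,
                    "q_w": lambda a: find_modules(
                        a,
                        n_restarts=int(config["null_restarts"]),
                        seed=seed,
                    ).qw,
                }
                null_reports[name] = {}
                for metric_name, fn in tests.items():
                    ensemble = null_test(
                        sub, fn, runs=runs, seed=seed, metric_name=metric_name
                    )
                    null_reports[name][metric_name] = ensemble.summary()
            save_json(null_reports, "nulls.json")
            completed.append(stage)
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc

    # --- stage: species ----------------------------------------------------
    stage = "species"
    try:
        tables_by_currency = {}
        for name, sub in trimmed.items():
            table = species_table(
                sub,
                partitions[name],
                group_map,
                degree_mode=str(config["degree_mode"]),
            )
            tables_by_currency[name] = table
            save_df(table, f"species_{name}.csv")
        completed.append(stage)
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # --- stage: compare ----------------------------------------------------
    stage = "compare"
    try:
        report = currency_report(
            matrices,
            partitions,
            tables_by_currency,
            null_results=null_reports or None,
            h2_mode=str(config["h2_mode"]),
        )
        path = out / "comparison_report.json"
        path.write_text(report_to_json(report) + "\n")
        artifacts["comparison_report.json"] = _sha256(path)
        completed.append(stage)
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    manifest = {
        "package_version": __version__,
        "config": config,
        "config_sha256": hashlib.sha256(config_blob.encode()).hexdigest(),
        "master_seed": master_seed,
        "stage_seeds": {s: stage_seed(master_seed, s) for s in STAGES},
        "completed_stages": completed,
        "artifacts": dict(sorted(artifacts.items())),
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, sort_keys=True, indent=2, default=str) + "\n"
    )
    return manifest
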