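"""Schema validation, run configuration and end-to-end orchestration.

Stages communicate through tidy CSV and JSON files on disk, so every
intermediate is inspectable and a run can be resumed from existing
outputs. A run is driven by a YAML config with one optional block per
stage (simulate / screen / uptake / mode / growth); the combined report
records every stage's outcome plus provenance (config hash, seed,
package version).
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .exo_screen import ResponseTable, classify_direction, compute_log2fc_cv, summarize_screen
from .growth_phenotype import GrowthCurve, estimate_lc50, growth_metrics_table, compare_strains
from .oocyte_uptake import call_uptake
from .synthetic_data import (
    GrowthSimParams,
    OocyteSimParams,
    SerumSimParams,
    TransporterTruth,
    simulate_growth_curves,
    simulate_oocyte_assay,
    simulate_serum_screen,
    write_growth_csv,
    write_oocyte_csv,
    write_serum_csv,
)
from .transport_mode import AssayConstants, call_modes

__all__ = [
    "ConfigError",
    "SchemaError",
    "RunConfig",
    "validate_table",
    "run_pipeline",
    "SCHEMAS",
]

log = logging.getLogger("deorphan")

STAGE_ORDER = ("simulate", "screen", "uptake", "mode", "growth")


class ConfigError(Exception):
    """Invalid run configuration."""


class SchemaError(Exception):
    """Input table does not match the declared schema."""


SCHEMAS: dict[str, dict] = {
    "serum": {
        "required": ["compound_id", "sample_id", "group", "replicate", "response"],
        "optional": ["class"],
        "numeric": {"response": (0.0, None)},
        "key": ["compound_id", "sample_id"],
        "categorical": {"group": ("control", "treated")},
    },
    "oocyte": {
        "required": ["transporter", "compound", "pool_id", "n_oocytes", "response"],
        "optional": [],
        "numeric": {"n_oocytes": (1.0, None), "response": (0.0, None)},
        "key": ["transporter", "compound", "pool_id"],
        "categorical": {},
    },
    "growth": {
        "required": ["strain", "condition", "conc_mM", "replicate", "time_h", "od"],
        "optional": [],
        "numeric": {"od": (0.0, None), "conc_mM": (0.0, None)},
        "key": ["strain", "condition", "conc_mM", "replicate", "time_h"],
        "categorical": {},
    },
}


def validate_table(
    source: str | Path | pd.DataFrame,
    schema_name: str,
    mapping: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, list[dict]]:
    """Read and validate a stage input table.

    Returns ``(table, violations)`` where each violation carries the
    1-based data row number (header excluded), the offending column and a
    message. Missing required columns or an empty file raise
    :class:`SchemaError` immediately — those are not row-level problems.
    """
    if schema_name not in SCHEMAS:
        raise ValueError(f"unknown schema {schema_name!r}")
    schema = SCHEMAS[schema_name]
    if isinstance(source, (str, Path)):
        try:
            df = pd.read_csv(source)
        except pd.errors.EmptyDataError as exc:
            raise SchemaError(f"empty input file {source}") from exc
    else:
        df = source.copy()
    if mapping:
        df = df.rename(columns=mapping)
    if df.empty:
        raise SchemaError(f"no data rows in {schema_name} table")

    missing = [c for c in schema["required"] if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{schema_name} table missing required columns {missing}; "
            f"available: {sorted(df.columns)}"
        )

    violations: list[dict] = []
    for col, (lo, hi) in schema["numeric"].items():
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | ~np.isfinite(vals)
        if lo is not None:
            bad |= vals < lo
        if hi is not None:
            bad |= vals > hi
        for idx in df.index[bad]:
            violations.append(dict(row=int(idx) + 1, column=col,
                                   message=f"value {df.at[idx, col]!r} out of range"))
        df[col] = vals
    for col, allowed in schema["categorical"].items():
        bad = ~df[col].isin(allowed)
        for idx in df.index[bad]:
            violations.append(dict(row=int(idx) + 1, column=col,
                                   message=f"value {df.at[idx, col]!r} not in {allowed}"))
    dup = df.duplicated(subset=schema["key"], keep=False)
    for idx in df.index[dup]:
        violations.append(dict(row=int(idx) + 1, column=",".join(schema["key"]),
                               message="duplicate key"))
    return df, violations


@dataclass
class RunConfig:
    """Parsed YAML run configuration."""

    stages: dict = field(default_factory=dict)
    seed: int = 0
    alpha: float = 0.05
    out_dir: Path = Path("deorphan_out")
    raw: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path, seed: int | None = None,
                  out_dir: str | Path | None = None) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigError("config must be a YAML mapping")
        return cls.from_dict(raw, seed=seed, out_dir=out_dir)

    @classmethod
    def from_dict(cls, raw: dict, seed: int | None = None,
                  out_dir: str | Path | None = None) -> "RunConfig":
        stages = {k: v for k, v in raw.items() if k in STAGE_ORDER}
        if not stages:
            raise ConfigError(f"config defines no stage blocks (expected one of {STAGE_ORDER})")
        alpha = float(raw.get("alpha", 0.05))
        if not 0.0 < alpha < 1.0:
            raise ConfigError("alpha must be in (0, 1)")
        cfg_seed = int(seed if seed is not None else raw.get("seed", 0))
        out = Path(out_dir if out_dir is not None else raw.get("out_dir", "deorphan_out"))
        return cls(stages=stages, seed=cfg_seed, alpha=alpha, out_dir=out, raw=raw)

    def content_hash(self) -> str:
        payload = json.dumps({"stages": self.stages, "seed": self.seed,
                              "alpha": self.alpha}, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _parse_truths(entries: list[dict]) -> list[TransporterTruth]:
    return [TransporterTruth(**e) for e in entries]


def _stage_simulate(cfg: RunConfig, out: Path, report: dict) -> dict[str, object]:
    block = cfg.stages["simulate"]
    produced: dict[str, object] = {}
    if "serum" in block:
        params = SerumSimParams(**{**block["serum"], "seed": block["serum"].get("seed", cfg.seed)})
        table, truth = simulate_serum_screen(params)
        write_serum_csv(table, out / "serum.csv")
        truth.to_json(out / "serum_truth.json")
        produced["serum_table"] = table
        report["outputs"].append("serum.csv")
    if "oocyte" in block:
        sub = block["oocyte"]
        params = OocyteSimParams(**{**sub.get("params", {}),
                                    "seed": sub.get("params", {}).get("seed", cfg.seed + 1)})
        truths = _parse_truths(sub.get("truths", []))
        meas, truth = simulate_oocyte_assay(truths, params)
        write_oocyte_csv(meas, out / "oocyte.csv")
        truth.to_json(out / "oocyte_truth.json")
        produced["oocyte_measurements"] = meas
        report["outputs"].append("oocyte.csv")
    if "growth" in block:
        params = GrowthSimParams(**{**block["growth"],
                                    "seed": block["growth"].get("seed", cfg.seed + 2)})
        curves, truth = simulate_growth_curves(params)
        write_growth_csv(curves, out / "growth.csv")
        truth.to_json(out / "growth_truth.json")
        produced["growth_curves"] = curves
        report["outputs"].append("growth.csv")
    return produced


def _stage_screen(cfg: RunConfig, out: Path, produced: dict, report: dict) -> None:
    block = cfg.stages["screen"] or {}
    if "input" in block:
        df, violations = validate_table(block["input"], "serum", block.get("mapping"))
        report["stages"]["screen"]["violations"] = len(violations)
        table = ResponseTable.from_tidy(df)
    elif "serum_table" in produced:
        table = produced["serum_table"]
    else:
        raise ConfigError("screen stage needs an input path or a simulate.serum block")
    stats = compute_log2fc_cv(table, pseudo=block.get("pseudo", "auto"))
    results = classify_direction(stats,
                                 fc_threshold=float(block.get("fc_threshold", 0.5)),
                                 cv_threshold=float(block.get("cv_threshold", 30.0)))
    summary = summarize_screen(results, table.compounds)
    results.to_csv(out / "screen_results.csv", index=False)
    (out / "screen_summary.json").write_text(json.dumps(summary, indent=2))
    report["outputs"] += ["screen_results.csv", "screen_summary.json"]
    report["screen_summary"] = summary
    report["stages"]["screen"]["rows"] = {"input": int(len(results)),
                                          "used": int(results["evaluable"].sum()),
                                          "excluded_not_evaluable":
                                              int((~results["evaluable"]).sum())}


def _load_oocyte(cfg: RunConfig, block: dict, produced: dict, report_entry: dict) -> pd.DataFrame:
    if "input" in block:
        df, violations = validate_table(block["input"], "oocyte", block.get("mapping"))
        report_entry["violations"] = len(violations)
        return df
    if "oocyte_measurements" in produced:
        return produced["oocyte_measurements"]
    raise ConfigError("uptake/mode stage needs an input path or a simulate.oocyte block")


def _stage_uptake(cfg: RunConfig, out: Path, produced: dict, report: dict) -> None:
    block = cfg.stages["uptake"] or {}
    meas = _load_oocyte(cfg, block, produced, report["stages"]["uptake"])
    calls = call_uptake(meas, alpha=float(block.get("alpha", cfg.alpha)),
                        equal_var=not block.get("welch", False),
                        bh=bool(block.get("bh", False)))
    calls.to_csv(out / "uptake_calls.csv", index=False)
    produced["uptake_calls"] = calls
    produced.setdefault("oocyte_measurements", meas)
    report["outputs"].append("uptake_calls.csv")
    report["n_uptake_calls"] = int(len(calls))


def _stage_mode(cfg: RunConfig, out: Path, produced: dict, report: dict) -> None:
    block = cfg.stages["mode"] or {}
    meas = _load_oocyte(cfg, block, produced, report["stages"]["mode"])
    if "uptake_calls" in produced:
        calls = produced["uptake_calls"]
    elif "uptake_calls" in block:
        calls = pd.read_csv(block["uptake_calls"])
    else:
        raise ConfigError("mode stage needs uptake calls (run uptake or point to a CSV)")
    constants = AssayConstants(
        c_medium_mM=float(block.get("c_medium", 2.0)),
        oocyte_volume_uL=float(block.get("oocyte_volume_uL", 1.0)),
        response_per_mM=float(block.get("response_per_mM", 1.0)),
    )
    modes = call_modes(meas, calls, constants, alpha=float(block.get("alpha", cfg.alpha)))
    modes.to_csv(out / "mode_calls.csv", index=False)
    produced["mode_calls"] = modes
    report["outputs"].append("mode_calls.csv")


def _curves_from_frame(df: pd.DataFrame) -> list[GrowthCurve]:
    curves = []
    for (strain, condition, conc, rep), sub in df.groupby(
            ["strain", "condition", "conc_mM", "replicate"], sort=False):
        sub = sub.sort_values("time_h")
        curves.append(GrowthCurve(strain=str(strain), condition=str(condition),
                                  conc_mM=float(conc), replicate=str(rep),
                                  times_h=sub["time_h"].to_numpy(dtype=float),
                                  od=sub["od"].to_numpy(dtype=float)))
    return curves


def _stage_growth(cfg: RunConfig, out: Path, produced: dict, report: dict) -> None:
    block = cfg.stages["growth"] or {}
    if "input" in block:
        df, violations = validate_table(block["input"], "growth", block.get("mapping"))
        report["stages"]["growth"]["violations"] = len(violations)
        curves = _curves_from_frame(df)
    elif "growth_curves" in produced:
        curves = produced["growth_curves"]
    else:
        raise ConfigError("growth stage needs an input path or a simulate.growth block")

    metric = block.get("metric", "max_od")
    if metric not in ("max_od", "mu_max"):
        raise ConfigError("growth metric must be max_od or mu_max")
    metrics = growth_metrics_table(curves, window=int(block.get("window", 5)),
                                   od_floor=float(block.get("od_floor", 0.01)),
                                   average=bool(block.get("average", False)))
    metrics.to_csv(out / "growth_metrics.csv", index=False)
    report["outputs"].append("growth_metrics.csv")

    dose_rows = []
    for (strain, condition), sub in metrics.groupby(["strain", "condition"]):
        per_conc = sub.groupby("conc_mM")[metric].mean()
        if per_conc.index.nunique() >= 4 and 0.0 in per_conc.index:
            try:
                dr = estimate_lc50(per_conc.index.to_numpy(), per_conc.to_numpy())
                dose_rows.append(dict(strain=strain, condition=condition,
                                      metric=metric, lc50_mM=dr.lc50_mM,
                                      method=dr.method))
            except ValueError as exc:
                dose_rows.append(dict(strain=strain, condition=condition,
                                      metric=metric, lc50_mM=np.nan,
                                      method=f"failed: {exc}"))
    if dose_rows:
        pd.DataFrame(dose_rows).to_csv(out / "dose_response.csv", index=False)
        report["outputs"].append("dose_response.csv")
        report["dose_response"] = dose_rows

    reference = block.get("reference")
    if reference is not None:
        comp_rows = []
        for (condition, conc), sub in metrics.groupby(["condition", "conc_mM"]):
            ref = sub[sub["strain"] == reference]
            if ref.empty:
                continue
            for strain, mut in sub[sub["strain"] != reference].groupby("strain"):
                comp = compare_strains(mut, ref, alpha=cfg.alpha)
                for _, row in comp.iterrows():
                    comp_rows.append(dict(strain=strain, condition=condition,
                                          conc_mM=conc, **row.to_dict()))
        if comp_rows:
            pd.DataFrame(comp_rows).to_csv(out / "strain_comparisons.csv", index=False)
            report["outputs"].append("strain_comparisons.csv")


_STAGE_FUNCS = {
    "screen": _stage_screen,
    "uptake": _stage_uptake,
    "mode": _stage_mode,
    "growth": _stage_growth,
}

# Downstream stages that cannot run once the named stage has failed.
_DEPENDENTS = {
    "simulate": ("screen", "uptake", "mode", "growth"),
    "uptake": ("mode",),
}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in dependency order.

    Returns the combined report (also written to ``report.json`` in the
    output directory). A failing stage is recorded with its error, its
    dependents are skipped, and ``report["ok"]`` is False.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "ok": True,
        "stages": {},
        "outputs": [],
        "provenance": {
            "config_hash": config.content_hash(),
            "seed": config.seed,
            "version": __version__,
        },
    }
    produced: dict[str, object] = {}
    failed: set[str] = set()

    for stage in STAGE_ORDER:
        if stage not in config.stages:
            continue
        blocked = [f for f in failed if stage in _DEPENDENTS.get(f, ())
                   and "input" not in (config.stages[stage] or {})]
        if blocked:
            report["stages"][stage] = {"status": "skipped",
                                       "reason": f"upstream failure in {blocked[0]}"}
            continue
        report["stages"][stage] = {"status": "ok"}
        log.info("running stage %s", stage)
        try:
            if stage == "simulate":
                produced.update(_stage_simulate(config, out, report))
            else:
                _STAGE_FUNCS[stage](config, out, produced, report)
        except Exception as exc:  # noqa: BLE001 - stage isolation is the contract
            log.error("stage %s failed: %s", stage, exc)
            report["stages"][stage] = {"status": "failed", "error": str(exc)}
            report["ok"] = False
            failed.add(stage)

    (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report
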