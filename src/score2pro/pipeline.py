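"""End-to-end pipeline driver: configuration handling, stage execution with
caching, structured JSON-line logging, and publication-style table outputs.

A run is described by a YAML/JSON config with sections ``simulation``,
``prep``, ``selection``, ``evaluation`` and optional ``optimism`` /
``region_cv`` blocks.  Stages execute in order simulate -> prep -> general ->
subgroups -> evaluate -> report; each stage's config-section hash is recorded
in the run manifest and unchanged early stages are skipped on re-runs.
Identical config + seed produces identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
import yaml

from .cohort_prep import PrepConfig, prepare
from .metrics import optimism_corrected_auc, region_cv
from .panel_select import (GBMParams, SelectionConfig, predict_risk,
                           train_classifier)
from .stratified import (EvalConfig, build_general_model,
                         compare_specific_vs_general, evaluate_high_risk,
                         panel_intersections, run_subgroup_pipeline,
                         sweep_composite_cells, table2_summary)
from .subgroups import STANDARD_SUBGROUPS
from .synthetic_cohort import (Cohort, SimConfig, apply_missingness,
                               read_cohort, simulate_cohort, write_cohort)

STAGES = ("simulate", "prep", "general", "subgroups", "evaluate", "report")

_KNOWN_SECTIONS = {"seed", "out_dir", "cohort_file", "simulation", "prep",
                   "selection", "evaluation", "subgroups", "optimism",
                   "region_cv"}


class ConfigError(ValueError):
    pass


def load_config(path: str | Path) -> dict:
    text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ConfigError("config root must be a mapping")
    unknown = set(cfg) - _KNOWN_SECTIONS
    if unknown:
        raise ConfigError(f"unknown config sections: {sorted(unknown)}")
    return cfg


def _build(section_cls, section: dict, path: str):
    try:
        return section_cls(**(section or {}))
    except TypeError as exc:
        raise ConfigError(f"config section {path!r}: {exc}") from None
    except ValueError as exc:
        raise ConfigError(f"config section {path!r}: {exc}") from None


def _hash_obj(obj: Any) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _digest_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


class JsonLogger:
    """Line-delimited JSON log, to a file and (optionally) stderr."""

    def __init__(self, path: Optional[Path] = None, echo: bool = True):
        self.path = path
        self.echo = echo
        if path is not None:
            path.parent.mkdir(parents=True, exist_ok=True)
            self._fh = open(path, "a")
        else:
            self._fh = None

    def log(self, stage: str, event: str, **fields) -> None:
        rec = {"ts": round(time.time(), 3), "stage": stage, "event": event,
               **fields}
        line = json.dumps(rec, default=str)
        if self._fh:
            self._fh.write(line + "\n")
            self._fh.flush()
        if self.echo:
            print(line, file=sys.stderr)

    def close(self) -> None:
        if self._fh:
            self._fh.close()


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    stages: dict = field(default_factory=dict)

    def record(self, stage: str, section_hash: str, outputs: list[Path],
               seconds: float) -> None:
        self.stages[stage] = {
            "section_hash": section_hash,
            "outputs": {str(p): _digest_file(p) for p in outputs if p.exists()},
            "seconds": round(seconds, 3),
        }

    def save(self, path: Path) -> None:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=1))

    @classmethod
    def load(cls, path: Path) -> Optional["RunManifest"]:
        if not path.exists():
            return None
        d = json.loads(path.read_text())
        return cls(config_hash=d["config_hash"], seed=d["seed"],
                   version=d.get("version", "?"), stages=d.get("stages", {}))


def _stage_fresh(prev: Optional[RunManifest], stage: str,
                 section_hash: str) -> bool:
    if prev is None or stage not in prev.stages:
        return False
    rec = prev.stages[stage]
    if rec["section_hash"] != section_hash:
        return False
    return all(Path(p).exists() and _digest_file(Path(p)) == h
               for p, h in rec["outputs"].items())


def run_pipeline(config: dict | str | Path, out_dir: str | Path,
                 seed: Optional[int] = None,
                 stop_after: Optional[str] = None,
                 echo_log: bool = False) -> RunManifest:
    """Execute the full pipeline under one config; returns the run manifest.

    ``seed`` overrides the config seed for every stochastic stage.  All
    outputs land under ``out_dir``; nothing is written elsewhere.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    from . import __version__
    seed = int(config.get("seed", 0) if seed is None else seed)
    logger = JsonLogger(out / "run_log.jsonl", echo=echo_log)
    prev = RunManifest.load(out / "manifest.json")
    manifest = RunManifest(config_hash=_hash_obj(config), seed=seed,
                           version=__version__)

    sim_section = dict(config.get("simulation") or {})
    prep_section = dict(config.get("prep") or {})
    sel_section = dict(config.get("selection") or {})
    eval_section = dict(config.get("evaluation") or {})
    subgroup_names = config.get("subgroups") or [s.name for s in
                                                 STANDARD_SUBGROUPS]

    def done(stage: str) -> bool:
        return stop_after is not None and STAGES.index(stage) >= \
            STAGES.index(stop_after)

    # --- simulate ----------------------------------------------------------
    cohort_path = out / "cohort.csv"
    sim_hash = _hash_obj({**sim_section, "seed": seed})
    t0 = time.time()
    if config.get("cohort_file"):
        src = Path(config["cohort_file"])
        logger.log("simulate", "skipped", reason=f"using {src}")
        cohort_path = src
    elif _stage_fresh(prev, "simulate", sim_hash):
        logger.log("simulate", "cached")
        manifest.stages["simulate"] = prev.stages["simulate"]
    else:
        sim_cfg = _build(SimConfig, {**sim_section, "seed": seed},
                         "simulation")
        cohort = simulate_cohort(sim_cfg)
        cohort = apply_missingness(cohort, sim_cfg, seed=seed + 1)
        write_cohort(cohort, cohort_path, sim_cfg)
        manifest.record("simulate", sim_hash,
                        [cohort_path,
                         cohort_path.with_suffix(".csv.json")],
                        time.time() - t0)
        logger.log("simulate", "done", n=len(cohort),
                    events=int(cohort.data["event"].sum()))
    if done("simulate"):
        manifest.save(out / "manifest.json")
        logger.close()
        return manifest

    # --- prep --------------------------------------------------------------
    prep_hash = _hash_obj({**prep_section, "seed": seed, "sim": sim_hash})
    prepared_path = out / "prepared.csv"
    t0 = time.time()
    if _stage_fresh(prev, "prep", prep_hash):
        logger.log("prep", "cached")
        manifest.stages["prep"] = prev.stages["prep"]
        prepared, _ = read_cohort(prepared_path)
    else:
        try:
            cohort, _ = read_cohort(cohort_path)
        except (pd.errors.ParserError, ValueError) as exc:
            raise ConfigError(f"cohort file {cohort_path}: {exc}") from None
        prep_cfg = _build(PrepConfig,
                          {**prep_section, "split_seed": seed}, "prep")
        prepared, report = prepare(cohort, prep_cfg,
                                   out_report=out / "prep_report.json")
        write_cohort(prepared, prepared_path)
        manifest.record("prep", prep_hash,
                        [prepared_path, out / "prep_report.json"],
                        time.time() - t0)
        logger.log("prep", "done",
                    proteins=report["n_proteins_retained"],
                    splits=report["splits"])
    if done("prep"):
        manifest.save(out / "manifest.json")
        logger.close()
        return manifest

    sel_cfg = _build(SelectionConfig, sel_section, "selection")
    sel_cfg.gbm_params.seed = seed
    ev_cfg = _build(EvalConfig, {**eval_section, "seed": seed}, "evaluation")

    # --- general model -----------------------------------------------------
    t0 = time.time()
    general = build_general_model(prepared, sel_cfg, ev_cfg)
    general["screen"].to_csv(out / "general_screen.csv", index=False)
    (out / "general_panel.json").write_text(
        json.dumps(general["panel_result"].to_dict(), indent=1))
    logger.log("general", "done",
                panel=general["panel"],
                seconds=round(time.time() - t0, 2))
    manifest.record("general", _hash_obj([sim_hash, prep_hash, sel_section,
                                          eval_section]),
                    [out / "general_screen.csv", out / "general_panel.json"],
                    time.time() - t0)
    if done("general"):
        manifest.save(out / "manifest.json")
        logger.close()
        return manifest

    # --- subgroup pipelines ------------------------------------------------
    t0 = time.time()
    outcomes = {}
    for name in subgroup_names:
        oc = run_subgroup_pipeline(
            prepared, name, sel_cfg, ev_cfg,
            general_model=general)
        outcomes[name] = oc
        logger.log("subgroups", "subgroup_done", subgroup=name,
                    skipped=oc.skipped,
                    panel=None if oc.panel is None else oc.panel.selected_panel)
    table2 = table2_summary(outcomes)
    table2.to_csv(out / "table2_subgroup_models.csv", index=False)
    svg = [c for c in (compare_specific_vs_general(oc, ev_cfg)
                       for oc in outcomes.values()) if c]
    (out / "specific_vs_general.json").write_text(json.dumps(svg, indent=1))
    panels = {n: (oc.panel.selected_panel if oc.panel else [])
              for n, oc in outcomes.items() if not oc.skipped}
    (out / "subgroup_panels.json").write_text(json.dumps(panels, indent=1))
    manifest.record("subgroups", _hash_obj([sim_hash, prep_hash, sel_section,
                                            eval_section, subgroup_names]),
                    [out / "table2_subgroup_models.csv",
                     out / "subgroup_panels.json",
                     out / "specific_vs_general.json"],
                    time.time() - t0)
    if done("subgroups"):
        manifest.save(out / "manifest.json")
        logger.close()
        return manifest

    # --- evaluation: intersections, high-risk composite, 32-cell sweep -----
    t0 = time.time()
    usable = {n: p for n, p in panels.items() if p}
    eval_outputs = []
    if usable:
        inter = panel_intersections(usable)
        inter["membership"].to_csv(out / "fig4_intersection_matrix.csv")
        inter["intersection_cells"].assign(
            proteins=lambda d: d["proteins"].map(";".join)
        ).to_csv(out / "fig4_intersection_cells.csv", index=False)
        eval_outputs += [out / "fig4_intersection_matrix.csv",
                         out / "fig4_intersection_cells.csv"]
    try:
        hr = evaluate_high_risk(prepared, outcomes,
                                general["panel"],
                                selection=sel_cfg, eval_config=ev_cfg)
        (out / "fig5_high_risk_reclassification.json").write_text(
            json.dumps(hr, indent=1))
        eval_outputs.append(out / "fig5_high_risk_reclassification.json")
    except ValueError as exc:
        logger.log("evaluate", "high_risk_skipped", reason=str(exc))
    sweep = sweep_composite_cells(prepared, outcomes, sel_cfg, ev_cfg)
    sweep.to_csv(out / "composite_cell_sweep.csv", index=False)
    eval_outputs.append(out / "composite_cell_sweep.csv")

    extras = {}
    opt_section = config.get("optimism") or {}
    if opt_section.get("enabled", False) and general["panel"]:
        deriv_df = prepared.data.loc[prepared.derivation_mask()]
        X = deriv_df[general["panel"]].to_numpy(dtype=float)
        y = deriv_df["event"].to_numpy(dtype=int)

        def _fp(Xtr, ytr, Xev, _gbm=sel_cfg.gbm_params):
            return predict_risk(train_classifier(Xtr, ytr, _gbm), Xev)

        extras["optimism"] = optimism_corrected_auc(
            X, y, _fp, n_boot=int(opt_section.get("n_boot", 500)), seed=seed)
        extras["optimism"].pop("optimism_per_resample", None)
    rcv_section = config.get("region_cv") or {}
    if rcv_section.get("enabled", False) and general["panel"]:
        X = prepared.data[general["panel"]].to_numpy(dtype=float)
        y = prepared.data["event"].to_numpy(dtype=int)

        def _fp(Xtr, ytr, Xev, _gbm=sel_cfg.gbm_params):
            return predict_risk(train_classifier(Xtr, ytr, _gbm), Xev)

        extras["region_cv"] = region_cv(
            X, y, prepared.data["region"].to_numpy(), _fp)
    if extras:
        (out / "extra_validation.json").write_text(
            json.dumps(extras, indent=1))
        eval_outputs.append(out / "extra_validation.json")
    manifest.record("evaluate", _hash_obj([sim_hash, prep_hash, sel_section,
                                           eval_section, opt_section,
                                           rcv_section]),
                    eval_outputs, time.time() - t0)
    logger.log("evaluate", "done", seconds=round(time.time() - t0, 2))

    manifest.save(out / "manifest.json")
    logger.close()
    return manifest
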