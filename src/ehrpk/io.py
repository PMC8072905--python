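"""Dataset CSV and run-configuration formats.

Dataset files are plain CSV with the header

    subject_id,route,time_h,conc_ng_ml,blq,dose_mg_kg,body_weight_g

one row per sample; ``conc_ng_ml`` may be empty only when ``blq`` is 1.
Times are hours, concentrations ng/mL, doses mg/kg. Each subject has one
route, one dose and unique times.

Run configuration is YAML with a fixed schema; unknown keys are rejected
so that typos cannot silently change an analysis.
"""

from __future__ import annotations

import csv
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import CohortSpec
from .datasets import SubjectDataset
from .fitting import FitConfig
from .model import Route, SolverConfig

__all__ = ["DATASET_COLUMNS", "DatasetError", "ConfigError", "RunConfig",
           "read_dataset", "write_dataset", "load_config", "config_hash"]

DATASET_COLUMNS = ["subject_id", "route", "time_h", "conc_ng_ml", "blq",
                   "dose_mg_kg", "body_weight_g"]


class DatasetError(ValueError):
    """Malformed dataset file; message carries the offending line number."""


class ConfigError(ValueError):
    """Invalid run configuration."""


def write_dataset(path, subjects: list[SubjectDataset]) -> None:
    """Write subjects to the dataset CSV dialect (stable formatting, so a
    fixed cohort spec and seed reproduce byte-identical files)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(DATASET_COLUMNS)
        for s in subjects:
            for _, r in s.records.iterrows():
                conc = "" if (r["blq"] and not np.isfinite(r["conc_ng_ml"])) \
                    else format(r["conc_ng_ml"], ".10g")
                w.writerow([s.subject_id, s.route.value,
                            format(r["time_h"], ".10g"), conc,
                            int(r["blq"]),
                            format(s.dose_mg_kg, ".10g"),
                            format(s.body_weight_g, ".10g")])


def _parse_row(row: dict, line: int) -> dict:
    def fail(msg: str):
        raise DatasetError(f"line {line}: {msg}")

    out = {}
    sid = (row.get("subject_id") or "").strip()
    if not sid:
        fail("empty subject_id")
    out["subject_id"] = sid
    try:
        out["route"] = Route(row["route"].strip())
    except (ValueError, AttributeError):
        fail(f"invalid route {row.get('route')!r}")
    for name in ("time_h", "dose_mg_kg", "body_weight_g"):
        try:
            out[name] = float(row[name])
        except (TypeError, ValueError):
            fail(f"field {name}: cannot parse {row.get(name)!r} as a number")
    blq_raw = (row.get("blq") or "").strip()
    if blq_raw not in ("0", "1"):
        fail(f"field blq must be 0 or 1, got {blq_raw!r}")
    out["blq"] = blq_raw == "1"
    conc_raw = (row.get("conc_ng_ml") or "").strip()
    if conc_raw == "":
        if not out["blq"]:
            fail("empty conc_ng_ml requires blq=1")
        out["conc_ng_ml"] = float("nan")
    else:
        try:
            out["conc_ng_ml"] = float(conc_raw)
        except ValueError:
            fail(f"field conc_ng_ml: cannot parse {conc_raw!r}")
        if out["conc_ng_ml"] < 0 and not out["blq"]:
            fail("negative conc_ng_ml requires blq=1")
    return out


def read_dataset(path) -> list[SubjectDataset]:
    """Read and validate a dataset CSV into typed per-subject datasets,
    ordered by subject then time."""
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != DATASET_COLUMNS:
            raise DatasetError(
                f"header mismatch: expected {DATASET_COLUMNS}, "
                f"got {reader.fieldnames}")
        rows = [ _parse_row(row, line)
                 for line, row in enumerate(reader, start=2) ]
    if not rows:
        raise DatasetError("dataset contains no records")
    by_subject: dict[str, list[dict]] = {}
    for r in rows:
        by_subject.setdefault(r["subject_id"], []).append(r)
    subjects = []
    for sid in sorted(by_subject):
        recs = by_subject[sid]
        for attr in ("route", "dose_mg_kg", "body_weight_g"):
            vals = {r[attr] for r in recs}
            if len(vals) != 1:
                raise DatasetError(
                    f"subject {sid}: inconsistent {attr} values {vals}")
        times = [r["time_h"] for r in recs]
        if len(set(times)) != len(times):
            dup = next(t for t in times if times.count(t) > 1)
            raise DatasetError(f"subject {sid}: duplicate time {dup} h")
        df = pd.DataFrame({"time_h": times,
                           "conc_ng_ml": [r["conc_ng_ml"] for r in recs],
                           "blq": [r["blq"] for r in recs]})
        subjects.append(SubjectDataset(
            subject_id=sid, route=recs[0]["route"],
            dose_mg_kg=recs[0]["dose_mg_kg"],
            body_weight_g=recs[0]["body_weight_g"], records=df))
    return subjects


# --- run configuration -----------------------------------------------------

_COHORT_KEYS = {"n_subjects", "param_means", "param_sds", "sigma",
                "lloq_ng_ml", "dose_mg_kg", "body_weight_mean_g",
                "body_weight_sd_g", "distribution", "n_transit", "times"}
_FIT_KEYS = {"n_starts", "perturb_factor", "bounds", "tol", "max_iter",
             "sigma_floor", "fixed", "polish"}
_SOLVER_KEYS = {"method", "rtol", "atol", "bile_mode", "bile_window_start"}
_TOP_KEYS = {"routes", "seed", "output_dir", "cohort", "fit", "solver"}


@dataclass
class RunConfig:
    """Validated pipeline configuration."""
    routes: list[Route] = field(default_factory=lambda: list(Route))
    seed: int = 0
    output_dir: str = "out"
    cohort: dict = field(default_factory=dict)
    fit: dict = field(default_factory=dict)
    solver: dict = field(default_factory=dict)

    def cohort_spec(self, route: Route, seed_offset: int = 0) -> CohortSpec:
        kw = dict(self.cohort)
        if "times" in kw and kw["times"] is not None:
            kw["times"] = tuple(float(t) for t in kw["times"])
        return CohortSpec(route=route, seed=self.seed + seed_offset, **kw)

    def fit_config(self) -> FitConfig:
        kw = dict(self.fit)
        if "bounds" in kw:
            kw["bounds"] = tuple(kw["bounds"])
        return FitConfig(seed=self.seed, solver=self.solver_config(), **kw)

    def solver_config(self) -> SolverConfig:
        return SolverConfig(**self.solver)


def _check_keys(section: dict, allowed: set[str], where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in {where}: {sorted(unknown)}")


def load_config(path_or_dict) -> RunConfig:
    """Load and schema-validate a YAML run configuration."""
    if isinstance(path_or_dict, dict):
        raw = path_or_dict
    else:
        with open(path_or_dict) as fh:
            raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("configuration must be a mapping")
    _check_keys(raw, _TOP_KEYS, "top level")
    for section, allowed in (("cohort", _COHORT_KEYS), ("fit", _FIT_KEYS),
                             ("solver", _SOLVER_KEYS)):
        sub = raw.get(section) or {}
        if not isinstance(sub, dict):
            raise ConfigError(f"section {section!r} must be a mapping")
        _check_keys(sub, allowed, f"section {section!r}")
    routes_raw = raw.get("routes", [r.value for r in Route])
    try:
        routes = [Route(r) for r in routes_raw]
    except ValueError as exc:
        raise ConfigError(f"invalid route in {routes_raw!r}") from exc
    cfg = RunConfig(routes=routes, seed=int(raw.get("seed", 0)),
                    output_dir=str(raw.get("output_dir", "out")),
                    cohort=dict(raw.get("cohort") or {}),
                    fit=dict(raw.get("fit") or {}),
                    solver=dict(raw.get("solver") or {}))
    # construct each sub-config once so invalid values fail before any work
    for route in cfg.routes:
        cfg.cohort_spec(route)
    cfg.fit_config()
    cfg.solver_config()
    return cfg


def config_hash(cfg: RunConfig) -> str:
    """Stable digest of a configuration, for run logs."""
    canon = yaml.safe_dump({
        "routes": [r.value for r in cfg.routes], "seed": cfg.seed,
        "cohort": cfg.cohort, "fit": cfg.fit, "solver": cfg.solver,
    }, sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]
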