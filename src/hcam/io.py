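"""Readers, writers and run configuration.

Input is a patient-level CSV (header required, UTF-8, "." decimal) with one
row per patient; a :class:`RunConfig` names which columns play which role.
Fitted models round-trip through a versioned JSON document; standardized
rate tables and replicate results are plain CSV.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data import HospitalDataset
from .model import FitResult, ModelParams
from .splines import SplineBasisSpec

__all__ = ["RunConfig", "load_dataset", "save_model", "load_model", "load_config"]

MODEL_DOC_VERSION = 1

log = logging.getLogger("hcam")


@dataclass
class RunConfig:
    """Column roles and pipeline settings for a run."""

    input: str = ""
    hospital_col: str = "hospital"
    outcome_col: str = "y"
    x_cols: list = field(default_factory=list)
    t_cols: list = field(default_factory=list)
    v_col: str = "v"
    model: str = "hcam"
    d: int = 3
    q: int = 3
    K_grid: list = field(default_factory=lambda: [0, 1, 2, 3])
    n_quad: int = 21
    selection: str = "bic"  # K selection criterion: bic | aic
    weights: str = "volume"  # uniform | volume | explicit
    bootstrap_B: int = 2000
    bootstrap_m: int = 2000
    level: float = 0.95
    seed: int = 0
    output_dir: str = "."
    drop_missing: bool = True
    drop_no_event_hospitals: bool = False

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def load_config(path) -> RunConfig:
    return RunConfig.from_file(path)


def load_dataset(path, config: RunConfig) -> tuple[HospitalDataset, dict]:
    """Load a patient CSV into a typed dataset, with a preprocessing report.

    Rows with missing values in the used columns are dropped when
    ``config.drop_missing`` (counted in the report); hospitals without any
    observed event are dropped when ``config.drop_no_event_hospitals``.
    """
    df = pd.read_csv(path)
    cols = [config.hospital_col, config.outcome_col, config.v_col]
    cols += list(config.x_cols) + list(config.t_cols)
    missing_cols = [c for c in cols if c not in df.columns]
    if missing_cols:
        raise ValueError(f"columns not found in {path}: {missing_cols}")

    report = {"rows_read": len(df), "rows_dropped_missing": 0, "hospitals_dropped_no_event": 0}
    used = df[cols]
    if config.drop_missing:
        keep = used.notna().all(axis=1)
        report["rows_dropped_missing"] = int((~keep).sum())
        df = df[keep]
    elif used.isna().any().any():
        raise ValueError("dataset contains missing values and drop_missing is off")

    yvals = df[config.outcome_col]
    if not yvals.isin([0, 1]).all():
        raise ValueError(f"outcome column {config.outcome_col!r} is not binary 0/1")

    if config.drop_no_event_hospitals:
        events = df.groupby(config.hospital_col)[config.outcome_col].sum()
        dead_hospitals = events[events == 0].index
        report["hospitals_dropped_no_event"] = int(len(dead_hospitals))
        df = df[~df[config.hospital_col].isin(dead_hospitals)]
    if not len(df):
        raise ValueError("no rows left after preprocessing")

    data = HospitalDataset(
        hospital_ids=df[config.hospital_col].astype(str).to_numpy(),
        y=df[config.outcome_col].to_numpy(),
        X=df[list(config.x_cols)].to_numpy(dtype=float),
        V=df[config.v_col].to_numpy(dtype=float),
        T=df[list(config.t_cols)].to_numpy(dtype=float) if config.t_cols else None,
    )
    report["rows_used"] = data.N
    report["hospitals"] = data.H
    log.info("loaded %d rows / %d hospitals from %s (%d rows dropped missing, "
             "%d hospitals dropped with no events)", data.N, data.H, path,
             report["rows_dropped_missing"], report["hospitals_dropped_no_event"])
    return data, report


def save_model(result: FitResult, path) -> None:
    """Serialize a fit to a versioned JSON document."""
    doc = {
        "version": MODEL_DOC_VERSION,
        "model": result.model,
        "basis": result.basis.to_dict(),
        "params": result.params.to_dict(),
        "hospital_ids": [str(h) for h in result.hospital_ids],
        "V": [float(v) for v in result.V],
        "b_modes": [float(b) for b in result.b_modes],
        "loglik": result.loglik,
        "aic": result.aic,
        "bic": result.bic,
        "n_free": result.n_free,
        "n_quad_points": result.n_quad_points,
        "converged": result.converged,
        "iterations": result.iterations,
        "random_effect_mean": result.random_effect_mean,
        "random_effect_variance": result.random_effect_variance,
        "k_table": result.k_table,
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_model(path) -> FitResult:
    doc = json.loads(Path(path).read_text())
    version = doc.get("version")
    if version != MODEL_DOC_VERSION:
        raise ValueError(
            f"model document version {version!r} is not supported "
            f"(this build reads version {MODEL_DOC_VERSION})"
        )
    return FitResult(
        model=doc["model"],
        params=ModelParams.from_dict(doc["params"]),
        basis=SplineBasisSpec.from_dict(doc["basis"]),
        hospital_ids=np.asarray(doc["hospital_ids"]),
        V=np.asarray(doc["V"], dtype=float),
        loglik=doc["loglik"],
        aic=doc["aic"],
        bic=doc["bic"],
        n_free=doc.get("n_free", 0),
        n_quad_points=doc["n_quad_points"],
        converged=doc["converged"],
        iterations=doc["iterations"],
        random_effect_mean=doc["random_effect_mean"],
        random_effect_variance=doc["random_effect_variance"],
        b_modes=np.asarray(doc["b_modes"], dtype=float),
        k_table=doc.get("k_table", []),
    )
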