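"""CSV/JSON input-output and the reproducibility manifest.

Index data use a long CSV schema — one row per observed (cohort, stage) cell
with columns ``cohort, stage, index, cv_ex`` (cv_ex may be empty) — so
missing cells are simply absent rows.  Covariate designs use the long schema
``cohort, process, covariate, value`` with the intercept written explicitly as
covariate ``x0``.  All numeric output keeps full double precision; rounding
happens only in human-readable report tables.
"""

from __future__ import annotations

import hashlib
import json
import platform
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .model_core import STAGES, PROCESSES, CovariateSet, IndexDataset
from .synthetic_data import StudyDataset

__all__ = [
    "read_index_csv",
    "write_index_csv",
    "read_covariates_csv",
    "write_covariates_csv",
    "write_truth_json",
    "write_posterior_csv",
    "RunManifest",
    "write_manifest",
]


def write_index_csv(data: IndexDataset, path) -> None:
    rows = []
    for i, s in enumerate(STAGES):
        for t in range(data.T):
            if not data.mask[i, t]:
                continue
            cv = ""
            if data.cv_ex is not None and np.isfinite(data.cv_ex[i, t]):
                cv = repr(float(data.cv_ex[i, t]))
            rows.append(
                {"cohort": t + 1, "stage": s, "index": repr(float(data.nhat[i, t])), "cv_ex": cv}
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_index_csv(path) -> IndexDataset:
    df = pd.read_csv(path, dtype={"stage": str})
    required = {"cohort", "stage", "index"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    dup = df.duplicated(subset=["cohort", "stage"])
    if dup.any():
        r = df[dup].iloc[0]
        raise ValueError(f"{path}: duplicate cell (cohort {r.cohort}, stage {r.stage})")
    bad_stage = ~df.stage.isin(STAGES)
    if bad_stage.any():
        r = df[bad_stage].iloc[0]
        raise ValueError(f"{path}: unknown stage {r.stage!r} at cohort {r.cohort}")
    if (df["index"] <= 0).any():
        r = df[df["index"] <= 0].iloc[0]
        raise ValueError(
            f"{path}: non-positive index at (cohort {r.cohort}, stage {r.stage}), "
            f"column 'index'"
        )
    T = int(df.cohort.max())
    nhat = np.full((4, T), np.nan)
    cv_ex = np.full((4, T), np.nan)
    mask = np.zeros((4, T), dtype=bool)
    has_cv = "cv_ex" in df.columns
    for _, r in df.iterrows():
        i, t = STAGES.index(r.stage), int(r.cohort) - 1
        nhat[i, t] = r["index"]
        mask[i, t] = True
        if has_cv and pd.notna(r["cv_ex"]) and str(r["cv_ex"]).strip() != "":
            cv_ex[i, t] = float(r["cv_ex"])
    if not np.isfinite(cv_ex).any():
        cv_ex = None
    return IndexDataset(nhat=np.where(mask, nhat, 1.0), cv_ex=cv_ex, mask=mask)


def write_covariates_csv(cov: CovariateSet, path) -> None:
    rows = []
    for p in PROCESSES:
        X = cov.design(p)
        for t in range(X.shape[0]):
            for j in range(X.shape[1]):
                rows.append(
                    {"cohort": t + 1, "process": p, "covariate": f"x{j}",
                     "value": repr(float(X[t, j]))}
                )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_covariates_csv(path) -> CovariateSet:
    df = pd.read_csv(path, dtype={"process": str, "covariate": str})
    required = {"cohort", "process", "covariate", "value"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    mats = {}
    for p in PROCESSES:
        sub = df[df.process == p]
        if sub.empty:
            raise ValueError(f"{path}: no covariate rows for process {p}")
        wide = sub.pivot(index="cohort", columns="covariate", values="value")
        wide = wide.sort_index()[sorted(wide.columns, key=lambda c: int(c.lstrip("x")))]
        if wide.isna().any().any():
            raise ValueError(f"{path}: missing covariate value for process {p}")
        mats["x" + p] = wide.to_numpy(dtype=float)
    return CovariateSet(**mats)


def write_truth_json(ds: StudyDataset, path) -> None:
    """Truth sidecar: generating parameters, latent states and true CVs."""
    payload = {
        "seed": ds.seed,
        "replicate": ds.replicate,
        "config": {
            "T": ds.config.T,
            "a": ds.config.a,
            "cv_range": list(ds.config.cv_range),
            "nA0": ds.config.nA0,
            "coefs": {p: list(ds.config.coefs[p]) for p in PROCESSES},
            "sigmaP": dict(ds.config.sigmaP),
            "psi": dict(ds.config.psi),
        },
        "latent_n": {s: ds.trajectory.stage(s).tolist() for s in STAGES},
        "rho": ds.trajectory.rho.tolist(),
        "phi": ds.trajectory.phi.tolist(),
        "true_cv": ds.true_cv.tolist(),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def write_posterior_csv(result, path) -> None:
    """Tidy posterior draws: chain, draw, parameter, value."""
    n_chains, n_draws, _ = result.draws.shape
    frames = []
    for j, name in enumerate(result.param_names):
        df = pd.DataFrame(
            {
                "chain": np.repeat(np.arange(n_chains), n_draws),
                "draw": np.tile(np.arange(n_draws), n_chains),
                "parameter": name,
                "value": result.draws[:, :, j].ravel(),
            }
        )
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record emitted once per CLI run."""

    command: str
    config: dict
    seeds: Dict[str, int]
    inputs: Dict[str, str] = field(default_factory=dict)
    outputs: Dict[str, str] = field(default_factory=dict)
    versions: Dict[str, str] = field(default_factory=dict)
    timestamp: str = ""

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def write_manifest(
    command: str,
    out_dir,
    config: dict,
    seeds: Dict[str, int],
    inputs: Optional[List] = None,
    outputs: Optional[List] = None,
) -> RunManifest:
    import stagessm

    out_dir = Path(out_dir)
    config_str = json.dumps(config, sort_keys=True, default=str)
    manifest = RunManifest(
        command=command,
        config={"hash": hashlib.sha256(config_str.encode()).hexdigest(), **config},
        seeds=seeds,
        inputs={str(p): _digest(Path(p)) for p in (inputs or [])},
        outputs={str(p): _digest(Path(p)) for p in (outputs or [])},
        versions={
            "stagessm": stagessm.__version__,
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "platform": platform.platform(),
        },
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    (out_dir / "manifest.json").write_text(json.dumps(manifest.to_dict(), indent=1))
    return manifest
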