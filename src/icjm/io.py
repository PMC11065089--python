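"""CSV readers/writers for the three-file dataset layout and run configuration.

A dataset is exchanged as three CSV files keyed by subject id:

* longitudinal — columns ``id, time, y`` (one row per measurement);
* survival     — columns ``id, L, R`` with ``R`` of ``inf``/``""``/``NA``
  meaning right-censored;
* covariates   — column ``id`` plus one column per covariate.

Censoring indicators are derived from (L, R); continuous covariates can be
standardized (mean 0, sd 1) on read.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import JointDataset

__all__ = ["RunConfig", "read_joint_csv", "write_joint_csv"]


@dataclass
class RunConfig:
    """Chain, prior-variant and spline settings for one fit."""

    variant: str = "BL"
    iters: int = 5000
    burnin: int = 1000
    thin: int = 1
    seed: int = 0
    J_mu: int = 3
    J_alpha: int = 3
    degree: int = 3
    standardize: bool = False

    def __post_init__(self) -> None:
        if not self.iters > self.burnin >= 0:
            raise ValueError("need iters > burnin >= 0")
        if self.degree not in (1, 2, 3):
            raise ValueError("degree must be 1, 2 or 3")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        """Load from YAML; keyword overrides win over file values."""
        with open(path) as fh:
            values = yaml.safe_load(fh) or {}
        values.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**values)

    def to_dict(self) -> dict:
        return {
            "variant": self.variant, "iters": self.iters, "burnin": self.burnin,
            "thin": self.thin, "seed": self.seed, "J_mu": self.J_mu,
            "J_alpha": self.J_alpha, "degree": self.degree,
            "standardize": self.standardize,
        }


def _parse_R(values: pd.Series) -> np.ndarray:
    out = np.empty(len(values))
    for i, v in enumerate(values):
        if pd.isna(v) or (isinstance(v, str) and v.strip().lower() in ("", "inf", "na")):
            out[i] = np.inf
        else:
            out[i] = float(v)
    return out


def read_joint_csv(long_path, surv_path, covar_path,
                   standardize: bool = False) -> JointDataset:
    """Assemble a validated :class:`JointDataset` from the three CSV files.

    Subject ids must coincide across files (order-insensitive); with
    ``standardize=True`` non-binary covariate columns are centered and scaled.
    """
    long_df = pd.read_csv(long_path, float_precision="round_trip")
    surv_df = pd.read_csv(surv_path, dtype={"R": object},
                          float_precision="round_trip")
    covar_df = pd.read_csv(covar_path, float_precision="round_trip")
    for df, cols, path in ((long_df, {"id", "time", "y"}, long_path),
                           (surv_df, {"id", "L", "R"}, surv_path),
                           (covar_df, {"id"}, covar_path)):
        missing = cols - set(df.columns)
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")

    surv_df = surv_df.sort_values("id").reset_index(drop=True)
    covar_df = covar_df.sort_values("id").reset_index(drop=True)
    ids = surv_df["id"].to_numpy()
    if not np.array_equal(np.unique(ids), np.sort(ids)):
        raise ValueError("duplicate subject ids in the survival table")
    if not np.array_equal(ids, covar_df["id"].to_numpy()):
        raise ValueError("subject ids differ between survival and covariate tables")
    long_ids = long_df["id"].to_numpy()
    unknown = np.setdiff1d(long_ids, ids)
    if unknown.size:
        raise ValueError(f"longitudinal table has unknown subject ids: {unknown[:5]}")

    id_to_idx = {sid: k for k, sid in enumerate(ids)}
    subj = np.array([id_to_idx[s] for s in long_ids])
    L = surv_df["L"].astype(float).to_numpy()
    R = _parse_R(surv_df["R"])
    bad = np.flatnonzero(~(L < R))
    if bad.size:
        raise ValueError(f"L >= R at survival rows {bad[:5].tolist()}")
    t = long_df["time"].astype(float).to_numpy()
    if np.any(t < 0) or np.any(L < 0):
        raise ValueError("negative times are not allowed")

    X = covar_df.drop(columns="id").to_numpy(dtype=float)
    if standardize:
        for j in range(X.shape[1]):
            col = X[:, j]
            if np.unique(col).size > 2:  # leave binary columns alone
                X[:, j] = (col - col.mean()) / col.std()

    return JointDataset(y=long_df["y"].astype(float).to_numpy(),
                        t_long=t, subj=subj, L=L, R=R, X=X)


def write_joint_csv(dataset: JointDataset, long_path, surv_path, covar_path) -> None:
    """Write a dataset in the three-file layout; round-trips losslessly."""
    ids = np.arange(dataset.n)
    pd.DataFrame({
        "id": dataset.subj, "time": dataset.t_long, "y": dataset.y,
    }).to_csv(long_path, index=False, float_format="%.17g")
    pd.DataFrame({"id": ids, "L": dataset.L, "R": dataset.R}).to_csv(
        surv_path, index=False, float_format="%.17g")
    cov = pd.DataFrame(dataset.X, columns=[f"x{j + 1}" for j in range(dataset.p)])
    cov.insert(0, "id", ids)
    cov.to_csv(covar_path, index=False, float_format="%.17g")
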