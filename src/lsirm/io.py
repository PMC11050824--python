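"""Readers, writers and run manifests.

Response CSVs come in two dialects.  Wide: first column person id, one
column per item, cells 0/1/empty (empty = missing).  Long: columns
``person,item,response``, absent pairs = missing.  All outputs are keyed
by person/item id, never by internal index.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .alignment import AlignedPosterior
from .model import ModelConfig, ResponseMatrix
from .sampling import PosteriorSamples, RunConfig

__all__ = [
    "RunManifest",
    "read_responses",
    "write_responses",
    "write_draws",
    "write_positions",
    "load_config",
]


@dataclass
class RunManifest:
    """Everything needed to reproduce a run: inputs, config echo, seed."""

    command: str
    inputs: dict
    model_config: dict
    run_config: dict
    seed: int
    version: str = "0.1.0"
    converged: bool | None = None
    created: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


def _validate_cell(raw: str, row_label: str, col_label: str) -> float:
    txt = str(raw).strip()
    if txt == "" or txt.lower() == "nan":
        return np.nan
    if txt in ("0", "1", "0.0", "1.0"):
        return float(txt)
    raise ValueError(
        f"non-binary response {raw!r} at person {row_label!r}, item {col_label!r}"
    )


def read_responses(path: str | Path, dialect: str = "wide") -> ResponseMatrix:
    """Read a response CSV into a validated ResponseMatrix."""
    path = Path(path)
    if dialect == "wide":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        person_ids = df.iloc[:, 0].astype(str).tolist()
        item_ids = [str(c) for c in df.columns[1:]]
        vals = np.empty((len(person_ids), len(item_ids)))
        for r, pid in enumerate(person_ids):
            for c, iid in enumerate(item_ids):
                vals[r, c] = _validate_cell(df.iloc[r, c + 1], pid, iid)
    elif dialect == "long":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        need = {"person", "item", "response"}
        if not need.issubset(df.columns):
            raise ValueError("long dialect needs columns person,item,response")
        person_ids = list(dict.fromkeys(df["person"].astype(str)))
        item_ids = list(dict.fromkeys(df["item"].astype(str)))
        vals = np.full((len(person_ids), len(item_ids)), np.nan)
        p_idx = {p: k for k, p in enumerate(person_ids)}
        i_idx = {i: k for k, i in enumerate(item_ids)}
        seen = set()
        for _, row in df.iterrows():
            key = (row["person"], row["item"])
            if key in seen:
                raise ValueError(f"duplicate person-item pair {key}")
            seen.add(key)
            vals[p_idx[row["person"]], i_idx[row["item"]]] = _validate_cell(
                row["response"], row["person"], row["item"]
            )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    observed = ~np.isnan(vals)
    return ResponseMatrix(
        values=np.where(observed, vals, 0),
        observed=observed,
        person_ids=person_ids,
        item_ids=item_ids,
    )


def write_responses(Y: ResponseMatrix, path: str | Path, dialect: str = "wide") -> None:
    path = Path(path)
    if dialect == "wide":
        cells = np.where(Y.observed, Y.values.astype(object), "")
        df = pd.DataFrame(cells, columns=Y.item_ids)
        df.insert(0, "person", Y.person_ids)
        df.to_csv(path, index=False)
    elif dialect == "long":
        rows = [
            (Y.person_ids[p], Y.item_ids[i], int(Y.values[p, i]))
            for p in range(Y.n_persons)
            for i in range(Y.n_items)
            if Y.observed[p, i]
        ]
        pd.DataFrame(rows, columns=["person", "item", "response"]).to_csv(
            path, index=False
        )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def write_draws(s: PosteriorSamples, path: str | Path) -> None:
    """Persist retained draws as one CSV row per draw, flattened columns."""
    cols: dict[str, np.ndarray] = {}
    n = s.n_chains * s.n_retained
    cols["chain"] = np.repeat(np.arange(s.n_chains), s.n_retained)
    cols["draw"] = np.tile(np.arange(s.n_retained), s.n_chains)
    th = s.pooled("theta")
    for p, pid in enumerate(s.person_ids):
        cols[f"theta[{pid}]"] = th[:, p]
    bb = s.pooled("b")
    for i, iid in enumerate(s.item_ids):
        cols[f"b[{iid}]"] = bb[:, i]
    cols["sigma2"] = s.pooled("sigma2")
    if s.log_lambda is not None:
        cols["log_lambda"] = s.pooled("log_lambda")
        xi = s.pooled("xi")
        zeta = s.pooled("zeta")
        K = xi.shape[2]
        for p, pid in enumerate(s.person_ids):
            for k in range(K):
                cols[f"xi[{pid},{k + 1}]"] = xi[:, p, k]
        for i, iid in enumerate(s.item_ids):
            for k in range(K):
                cols[f"zeta[{iid},{k + 1}]"] = zeta[:, i, k]
    cols["log_posterior"] = s.pooled("log_posterior")
    assert all(v.shape[0] == n for v in cols.values())
    pd.DataFrame(cols).to_csv(path, index=False)


def write_positions(a: AlignedPosterior, path: str | Path) -> None:
    """Aligned posterior-mean positions: persons then items, one row each."""
    s = a.samples
    K = a.xi_mean.shape[1]
    rows = []
    for p, pid in enumerate(s.person_ids):
        rows.append([pid, "person", *a.xi_mean[p]])
    for i, iid in enumerate(s.item_ids):
        rows.append([iid, "item", *a.zeta_mean[i]])
    pd.DataFrame(
        rows, columns=["id", "role", *[f"dim{k + 1}" for k in range(K)]]
    ).to_csv(path, index=False)


def load_config(path: str | Path) -> tuple[ModelConfig, RunConfig]:
    """Read a YAML key-value config; unknown keys raise."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    model_keys = {f.name for f in dataclasses.fields(ModelConfig)}
    run_keys = {f.name for f in dataclasses.fields(RunConfig)}
    mc, rc = {}, {}
    for key, val in raw.items():
        if key in model_keys:
            mc[key] = val
        elif key in run_keys:
            rc[key] = val
        else:
            raise ValueError(f"unknown config key {key!r}")
    return ModelConfig(**mc), RunConfig(**rc)
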