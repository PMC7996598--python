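"""Readers, writers and configuration for the analysis pipelines.

File conventions: comma-separated UTF-8 tables with a header row and
period decimal separator; configuration as YAML (JSON is a YAML subset
and parses identically).  Concentrations are normalized to g/L on ingest —
tables declaring mg/L are divided by 1000 and the conversion is logged.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .equilibria import EquilibriumPoint
from .model import (
    ChemostatState,
    CommunityModel,
    OperatingConditions,
    Trajectory,
)
from .tracking import ReferenceSignal, TrackingResult

__all__ = [
    "load_model_config",
    "dump_model_config",
    "read_abundance_table",
    "write_abundance_table",
    "read_operating_log",
    "write_operating_log",
    "trajectory_frame",
    "write_trajectory",
    "equilibria_frame",
    "write_equilibria_report",
    "tracking_frame",
    "write_tracking_result",
    "RunManifest",
]

logger = logging.getLogger(__name__)

_UNIT_FACTORS = {"g/L": 1.0, "mg/L": 1e-3}


class TableFormatError(ValueError):
    """Malformed tabular input; the message names file, row and column."""


# ---------------------------------------------------------------------------
# model configuration
# ---------------------------------------------------------------------------


def load_model_config(path: str | Path) -> tuple[CommunityModel, OperatingConditions | None]:
    """Parse a model configuration file.

    Expected blocks::

        kinetics:
          - {otu: 1, group: G1, mu_max: 0.77, K: 0.7, inv_yield: 3.98}
          - ...
        units: {K: g/L}            # optional; mg/L triggers /1000
        interactions: [[...], ...] # optional dense n x n matrix; default 0
        operating:                 # optional
          horizon: 300.0
          segments:
            - {t_start: 0.0, D: 0.24, s_in: 1.25}
    """
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "kinetics" not in cfg:
        raise TableFormatError(f"{path}: missing 'kinetics' block")
    rows = cfg["kinetics"]
    k_unit = str(cfg.get("units", {}).get("K", "g/L"))
    if k_unit not in _UNIT_FACTORS:
        raise TableFormatError(f"{path}: unknown K unit '{k_unit}' (use g/L or mg/L)")
    factor = _UNIT_FACTORS[k_unit]
    if factor != 1.0:
        logger.info("%s: converting K from %s to g/L (x %g)", path, k_unit, factor)
    groups, mu_max, K, inv_y = [], [], [], []
    for i, row in enumerate(rows):
        try:
            g = str(row["group"]).upper()
            if g not in ("G1", "G2", "1", "2"):
                raise KeyError("group")
            groups.append(1 if g in ("G1", "1") else 2)
            mu_max.append(float(row["mu_max"]))
            K.append(float(row["K"]) * factor)
            inv_y.append(float(row["inv_yield"]))
        except (KeyError, TypeError, ValueError) as exc:
            raise TableFormatError(f"{path}: kinetics entry {i}: bad or missing field ({exc})")
    A = cfg.get("interactions")
    if A is not None:
        A = np.asarray(A, dtype=float)
        if A.shape != (len(rows), len(rows)):
            raise TableFormatError(f"{path}: interactions must be {len(rows)}x{len(rows)}")
    model = CommunityModel.build(groups, mu_max, K, inv_y, A=A)
    operating = None
    if "operating" in cfg:
        op = cfg["operating"]
        try:
            segments = [(float(s["t_start"]), float(s["D"]), float(s["s_in"])) for s in op["segments"]]
            operating = OperatingConditions(segments, horizon=float(op["horizon"]))
        except (KeyError, TypeError, ValueError) as exc:
            raise TableFormatError(f"{path}: operating block: {exc}")
    return model, operating


def dump_model_config(
    model: CommunityModel, path: str | Path, operating: OperatingConditions | None = None
) -> None:
    cfg: dict = {
        "kinetics": [
            {
                "otu": i + 1,
                "group": f"G{int(g)}",
                "mu_max": float(model.kinetics.mu_max[i]),
                "K": float(model.kinetics.K[i]),
                "inv_yield": float(model.kinetics.inv_yield[i]),
            }
            for i, g in enumerate(model.grouping.groups)
        ],
        "units": {"K": "g/L"},
        "interactions": model.interactions.A.tolist(),
    }
    if operating is not None:
        cfg["operating"] = {
            "horizon": operating.horizon,
            "segments": [
                {"t_start": t, "D": d, "s_in": s} for t, d, s in operating.segments
            ],
        }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# abundance tables and operating logs
# ---------------------------------------------------------------------------


def read_abundance_table(path: str | Path) -> tuple[ReferenceSignal, list[int]]:
    """Read a tidy abundance table into a reference signal.

    Columns: ``time_d, otu_id, conc, unit, group`` with unit in {g/L,
    mg/L} (mg/L converted) and group in {G1, G2}.  Returns the signal
    (columns ordered by first appearance of each OTU) and the group codes
    (1/2) per OTU.  Mixed group labels for one OTU, negative values and
    duplicate (time, otu) rows are rejected with row-level diagnostics.
    """
    path = Path(path)
    df = pd.read_csv(path)
    required = {"time_d", "otu_id", "conc", "unit", "group"}
    missing = required - set(df.columns)
    if missing:
        raise TableFormatError(f"{path}: missing column(s) {sorted(missing)}")
    for col, row_idx in zip(df["unit"], df.index):
        if col not in _UNIT_FACTORS:
            raise TableFormatError(f"{path}: row {row_idx}: unknown unit '{col}'")
    conc = df["conc"].astype(float) * df["unit"].map(_UNIT_FACTORS)
    if (df["unit"] == "mg/L").any():
        logger.info("%s: mg/L values converted to g/L", path)
    neg = conc < 0
    if neg.any():
        raise TableFormatError(
            f"{path}: row {int(np.flatnonzero(neg)[0])}: negative concentration (column conc)"
        )
    dup = df.duplicated(subset=["time_d", "otu_id"])
    if dup.any():
        raise TableFormatError(
            f"{path}: row {int(np.flatnonzero(dup)[0])}: duplicate (time_d, otu_id) pair"
        )
    groups: dict[str, int] = {}
    for row_idx, (otu, g) in enumerate(zip(df["otu_id"], df["group"])):
        g = str(g).upper()
        if g not in ("G1", "G2"):
            raise TableFormatError(f"{path}: row {row_idx}: bad group '{g}' (column group)")
        code = 1 if g == "G1" else 2
        if groups.setdefault(otu, code) != code:
            raise TableFormatError(
                f"{path}: row {row_idx}: OTU '{otu}' carries mixed group labels"
            )
    otus = list(dict.fromkeys(df["otu_id"]))
    wide = (
        df.assign(conc_gL=conc)
        .pivot(index="time_d", columns="otu_id", values="conc_gL")
        .reindex(columns=otus)
        .sort_index()
    )
    if wide.isna().any().any():
        t_bad = wide.index[wide.isna().any(axis=1)][0]
        raise TableFormatError(f"{path}: incomplete sampling at time_d={t_bad}")
    signal = ReferenceSignal(times=wide.index.to_numpy(float), values=wide.to_numpy(float))
    return signal, [groups[o] for o in otus]


def write_abundance_table(
    signal: ReferenceSignal, groups: list[int], path: str | Path
) -> None:
    rows = []
    for ti, row in zip(signal.times, signal.values):
        for j, v in enumerate(row):
            rows.append(
                {
                    "time_d": ti,
                    "otu_id": f"otu{j+1}",
                    "conc": v,
                    "unit": "g/L",
                    "group": f"G{groups[j]}",
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_operating_log(path: str | Path, horizon: float | None = None) -> OperatingConditions:
    """Operating log: columns ``time_d, D_per_day, s_in_g_per_L``; each row
    starts a piecewise-constant segment.  The horizon defaults to the last
    row's time if it carries NaN controls, else must be passed."""
    df = pd.read_csv(path)
    required = {"time_d", "D_per_day", "s_in_g_per_L"}
    if required - set(df.columns):
        raise TableFormatError(f"{path}: missing column(s) {sorted(required - set(df.columns))}")
    segs = [
        (float(r.time_d), float(r.D_per_day), float(r.s_in_g_per_L))
        for r in df.itertuples()
        if not (np.isnan(r.D_per_day) or np.isnan(r.s_in_g_per_L))
    ]
    if horizon is None:
        last = df.iloc[-1]
        if np.isnan(last.D_per_day):
            horizon = float(last.time_d)
        else:
            raise TableFormatError(
                f"{path}: horizon not given and last row is a live segment"
            )
    return OperatingConditions(segs, horizon=horizon)


def write_operating_log(operating: OperatingConditions, path: str | Path) -> None:
    rows = [
        {"time_d": t, "D_per_day": d, "s_in_g_per_L": s} for t, d, s in operating.segments
    ]
    rows.append({"time_d": operating.horizon, "D_per_day": np.nan, "s_in_g_per_L": np.nan})
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------


def trajectory_frame(traj: Trajectory) -> pd.DataFrame:
    """Tidy long format: time_d, variable (x_1.., s1..s3), value_g_per_L."""
    n = traj.n
    names = [f"x_{i+1}" for i in range(n)] + ["s1", "s2", "s3"]
    rows = []
    for ti, state in zip(traj.times, traj.states):
        for name, v in zip(names, state):
            rows.append({"time_d": ti, "variable": name, "value_g_per_L": v})
    return pd.DataFrame(rows)


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    trajectory_frame(traj).to_csv(path, index=False)


def equilibria_frame(points: list[EquilibriumPoint]) -> pd.DataFrame:
    rows = []
    for p in points:
        row = {"active_set": "+".join(f"x{i+1}" for i in p.survivors) or "-"}
        row.update({f"x_{i+1}": v for i, v in enumerate(p.x)})
        row.update({"s1": p.s[0], "s2": p.s[1], "s3": p.s[2]})
        row["max_Re_eigenvalue"] = float(p.eigenvalues.real.max())
        row["stability"] = p.stability
        rows.append(row)
    return pd.DataFrame(rows)


def write_equilibria_report(points: list[EquilibriumPoint], path: str | Path) -> None:
    equilibria_frame(points).to_csv(path, index=False)


def tracking_frame(result: TrackingResult) -> pd.DataFrame:
    """Wide table of controls, tracked states and reconstructed growth."""
    n = result.x.shape[1]
    data = {"time_d": result.times}
    for i in range(n):
        data[f"u_{i+1}"] = result.u[:, i]
    for i in range(n):
        data[f"x_{i+1}_g_per_L"] = result.x[:, i]
    for k in range(3):
        data[f"s{k+1}_g_per_L"] = result.s[:, k]
    mu = result.growth
    for i in range(n):
        data[f"mu_{i+1}_per_day"] = mu[:, i]
    return pd.DataFrame(data)


def write_tracking_result(result: TrackingResult, path: str | Path) -> None:
    tracking_frame(result).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# run manifest
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RunManifest:
    """Reproducibility record every pipeline run writes next to its outputs."""

    command: str
    config_hash: str
    seed: int | None
    outputs: tuple[str, ...]
    started_utc: str
    versions: dict

    @classmethod
    def create(
        cls, command: str, config_obj, seed: int | None, outputs: list[str | Path]
    ) -> "RunManifest":
        blob = json.dumps(config_obj, sort_keys=True, default=str).encode()
        import chemotrack

        return cls(
            command=command,
            config_hash=hashlib.sha256(blob).hexdigest()[:16],
            seed=seed,
            outputs=tuple(str(o) for o in outputs),
            started_utc=datetime.now(timezone.utc).isoformat(timespec="seconds"),
            versions={
                "chemotrack": chemotrack.__version__,
                "numpy": np.__version__,
                "python": platform.python_version(),
            },
        )

    def write(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.__dict__, fh, indent=2, default=str)
            fh.write("\n")
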