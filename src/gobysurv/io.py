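"""CSV formats and run configuration.

All pipeline artifacts are plain UTF-8 CSV with "." as the decimal
separator:

* haul table: ``trip_id,haul_id,n_total,n0_alive,nf_alive,t_hours,depth_m,temp0_C,tempf_C,oxygen``
* speed bins: ``fish_id,period,bin_index,speed_mm_s`` (plus ``haul_id``)
* trajectories: ``fish_id,frame,x_px,y_px,imputed``
* relative-survival grid (long): ``depth_m,temp_C,relative_survival``
* posterior draws (long): ``chain,iter,parameter,value``
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from gobysurv.inference import MCMCConfig, PosteriorSamples
from gobysurv.survival import HaulObservation
from gobysurv.tracking import Trajectory
from gobysurv.vitality import N_BINS, SpeedSeries

__all__ = [
    "HAUL_COLUMNS",
    "read_haul_csv",
    "write_haul_csv",
    "read_speeds_csv",
    "write_speeds_csv",
    "write_trajectories_csv",
    "write_grid_csv",
    "write_summary",
    "write_draws_csv",
    "RunConfig",
]

HAUL_COLUMNS = [
    "trip_id", "haul_id", "n_total", "n0_alive", "nf_alive",
    "t_hours", "depth_m", "temp0_C", "tempf_C", "oxygen",
]


def read_haul_csv(path: str | Path) -> list[HaulObservation]:
    """Read and validate a haul table; errors carry the offending line number."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in HAUL_COLUMNS if c not in df.columns and c != "oxygen"]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    hauls = []
    for pos, (_, row) in enumerate(df.iterrows()):
        line = pos + 2  # header is line 1
        try:
            oxygen = row.get("oxygen", None)
            oxygen = None if oxygen is None or pd.isna(oxygen) else float(oxygen)
            hauls.append(
                HaulObservation(
                    trip_id=str(row["trip_id"]),
                    haul_id=str(row["haul_id"]),
                    n_total=int(row["n_total"]),
                    n0_alive=int(row["n0_alive"]),
                    nf_alive=int(row["nf_alive"]),
                    t_hours=float(row["t_hours"]),
                    depth_m=float(row["depth_m"]),
                    temp0_C=float(row["temp0_C"]),
                    tempf_C=float(row["tempf_C"]),
                    oxygen=oxygen,
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}, line {line}: {exc}") from exc
    return hauls


def write_haul_csv(path: str | Path, hauls: Sequence[HaulObservation]) -> None:
    pd.DataFrame([vars(h) for h in hauls], columns=HAUL_COLUMNS).to_csv(
        path, index=False
    )


def write_speeds_csv(path: str | Path, series: Sequence[SpeedSeries]) -> None:
    rows = []
    for s in series:
        for period, values in (("before", s.before), ("after", s.after)):
            for b, v in enumerate(values):
                rows.append((s.haul_id, s.fish_id, period, b, v))
    pd.DataFrame(
        rows, columns=["haul_id", "fish_id", "period", "bin_index", "speed_mm_s"]
    ).to_csv(path, index=False)


def read_speeds_csv(path: str | Path) -> list[SpeedSeries]:
    df = pd.read_csv(path)
    out = []
    for (haul, fish), g in df.groupby(["haul_id", "fish_id"], sort=True):
        parts = {}
        for period in ("before", "after"):
            sub = g[g["period"] == period].sort_values("bin_index")
            if len(sub) != N_BINS:
                raise ValueError(
                    f"{path}: fish {fish} has {len(sub)} '{period}' bins, need {N_BINS}"
                )
            parts[period] = sub["speed_mm_s"].to_numpy()
        out.append(SpeedSeries(str(haul), str(fish), parts["before"], parts["after"]))
    return out


def write_trajectories_csv(path: str | Path, trajectories: Sequence[Trajectory]) -> None:
    rows = []
    for t in trajectories:
        for f, ((x, y), imp) in enumerate(zip(t.positions, t.imputed)):
            rows.append((t.fish_id, f, x, y, int(imp)))
    pd.DataFrame(rows, columns=["fish_id", "frame", "x_px", "y_px", "imputed"]).to_csv(
        path, index=False
    )


def write_grid_csv(path: str | Path, depths, temps, values) -> None:
    """Relative-survival surface in long format."""
    dd, tt = np.meshgrid(depths, temps, indexing="ij")
    pd.DataFrame(
        {
            "depth_m": dd.ravel(),
            "temp_C": tt.ravel(),
            "relative_survival": np.asarray(values).ravel(),
        }
    ).to_csv(path, index=False)


def write_summary(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=True, index_label="parameter")


def write_draws_csv(path: str | Path, samples: PosteriorSamples) -> None:
    samples.to_dataframe().to_csv(path, index=False)


@dataclass
class RunConfig:
    """End-to-end run configuration (YAML-serialisable).

    ``oxygen_threshold`` excludes hauls whose container oxygen at port fell
    below it; ``centering`` optionally overrides the sample-mean reference.
    """

    seed: int = 0
    out_dir: str = "results"
    haul_csv: str | None = None
    speeds_csv: str | None = None
    oxygen_threshold: float = -np.inf
    centering: dict | None = None
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    tracking: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        mcmc = MCMCConfig(**raw.pop("mcmc", {}))
        return cls(mcmc=mcmc, **raw)

    def to_yaml(self, path: str | Path) -> None:
        data = {k: v for k, v in vars(self).items() if k != "mcmc"}
        data["mcmc"] = {
            k: v for k, v in vars(self.mcmc).items() if not k.startswith("_")
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
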