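"""CSV serialization of trajectories, sweeps, assignments and thresholds."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .networks import Network, StrategyAssignment, read_edge_list, write_edge_list
from .experiments import SweepResult, Trajectory

__all__ = [
    "read_edge_list",
    "write_edge_list",
    "write_trajectory",
    "write_strategy_assignment",
    "read_strategy_assignment",
    "write_sweep",
    "threshold_table",
]


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write the per-round log (falls back to fractions if no stats kept)."""
    if traj.stats is not None:
        traj.stats.to_csv(path, index=False)
    else:
        pd.DataFrame(
            {"round": np.arange(len(traj.fraction_c)), "fraction_C": traj.fraction_c}
        ).to_csv(path, index=False)


def write_strategy_assignment(assignment: StrategyAssignment, path: str | Path) -> None:
    pd.DataFrame(
        {
            "node": np.arange(len(assignment.is_c)),
            "strategy": np.where(assignment.is_c, "C", "D"),
        }
    ).to_csv(path, index=False)


def read_strategy_assignment(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path)
    out = np.zeros(len(df), dtype=bool)
    out[df["node"].to_numpy()] = df["strategy"].to_numpy() == "C"
    return out


def write_sweep(result: SweepResult, out_dir: str | Path, stem: str = "sweep") -> None:
    """Write the replicate table and the threshold summary."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    result.table.to_csv(out_dir / f"{stem}_replicates.csv", index=False)
    summary = result.summary()
    summary.to_csv(out_dir / f"{stem}_summary.csv", index=False)
    pd.DataFrame(
        [
            {
                "r_inv": result.r_inv,
                "r_fix": result.r_fix,
                "initial_fraction": result.initial_fraction,
            }
        ]
    ).to_csv(out_dir / f"{stem}_thresholds.csv", index=False)


def threshold_table(k_max: int, h: int, delta_d: float) -> pd.DataFrame:
    """One-row analytic threshold report for (k_max, h, delta_d)."""
    from .predictive import (
        fixation_threshold_bound,
        fixation_threshold_infinite,
        p_cd_limit,
    )

    return pd.DataFrame(
        [
            {
                "k_max": k_max,
                "h": h,
                "delta_d": delta_d,
                "P_CD_inf": p_cd_limit(delta_d),
                "R_fix_inf": fixation_threshold_infinite(k_max, delta_d),
                "R_fix_bound": fixation_threshold_bound(k_max, h, delta_d)
                if h >= 2
                else float("nan"),
            }
        ]
    )
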