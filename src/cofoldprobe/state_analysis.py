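"""Bound/unbound occupancy analysis of ligand-RMSD time series.

Each frame of a (post-processed, unbiased or externally reweighted) series
is labelled *bound* when its ligand RMSD to the native pose is strictly
below the threshold (default 2.0 Å); every stable state outside the pocket
collapses into a single *unbound* class. Occupancy probabilities are frame
fractions per replicate, aggregated as mean ± sample (n−1) standard
deviation over replicates, following the triplicate convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BOUND_THRESHOLD",
    "StateSeries",
    "OccupancyEstimate",
    "classify_states",
    "occupancy",
    "aggregate_replicates",
    "read_rmsd_series",
    "occupancy_table",
]

BOUND_THRESHOLD = 2.0


@dataclass
class StateSeries:
    """Per-frame RMSD values and derived bound/unbound labels."""

    rmsd: np.ndarray
    labels: np.ndarray  # boolean, True = bound
    threshold: float = BOUND_THRESHOLD
    replicate_id: int = 0

    def __post_init__(self) -> None:
        self.rmsd = np.asarray(self.rmsd, dtype=float)
        self.labels = np.asarray(self.labels, dtype=bool)
        if self.rmsd.shape != self.labels.shape:
            raise ValueError("labels length must equal rmsd length")

    @property
    def n_frames(self) -> int:
        return int(self.rmsd.size)


@dataclass
class OccupancyEstimate:
    """Replicate-aggregated occupancy probabilities (mean ± sd)."""

    p_bound: float
    p_unbound: float
    sd_bound: float
    sd_unbound: float
    n_replicates: int
    single_replicate: bool = False

    def __str__(self) -> str:
        return (
            f"bound {self.p_bound:.2f} ± {self.sd_bound:.2f} / "
            f"unbound {self.p_unbound:.2f} ± {self.sd_unbound:.2f} "
            f"(n={self.n_replicates})"
        )


def classify_states(
    rmsd_series: Sequence[float],
    threshold: float = BOUND_THRESHOLD,
    replicate_id: int = 0,
) -> StateSeries:
    """Label frames bound (RMSD < threshold, strict) or unbound."""
    rmsd = np.asarray(rmsd_series, dtype=float)
    if rmsd.size == 0:
        raise ValueError("empty RMSD series")
    if np.any(rmsd < 0) or not np.all(np.isfinite(rmsd)):
        raise ValueError("RMSD values must be finite and non-negative")
    return StateSeries(
        rmsd=rmsd, labels=rmsd < threshold, threshold=threshold,
        replicate_id=replicate_id,
    )


def occupancy(series: StateSeries) -> tuple[float, float]:
    """(p_bound, p_unbound) frame fractions for one replicate; sums to 1.

    Pure counting — the result is invariant to frame order.
    """
    p_bound = float(np.mean(series.labels))
    return p_bound, 1.0 - p_bound


def aggregate_replicates(
    estimates: Sequence[tuple[float, float]]
) -> OccupancyEstimate:
    """Mean and sample (n−1) standard deviation over replicates."""
    if not len(estimates):
        raise ValueError("no replicate estimates")
    bound = np.array([b for b, _ in estimates], dtype=float)
    unbound = np.array([u for _, u in estimates], dtype=float)
    single = len(estimates) == 1
    sd_b = 0.0 if single else float(np.std(bound, ddof=1))
    sd_u = 0.0 if single else float(np.std(unbound, ddof=1))
    return OccupancyEstimate(
        p_bound=float(bound.mean()),
        p_unbound=float(unbound.mean()),
        sd_bound=sd_b,
        sd_unbound=sd_u,
        n_replicates=len(estimates),
        single_replicate=single,
    )


def read_rmsd_series(path: str | Path) -> np.ndarray:
    """Read a (frame, RMSD Å) CSV/whitespace table; returns the RMSD column."""
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    col = df.columns[-1]
    return df[col].to_numpy(dtype=float)


def occupancy_table(
    systems: dict[str, Sequence[Sequence[float]]],
    threshold: float = BOUND_THRESHOLD,
) -> pd.DataFrame:
    """Occupancy summary table: one row per system from replicate series."""
    rows = []
    for name, replicates in systems.items():
        per_rep = [
            occupancy(classify_states(series, threshold=threshold, replicate_id=i))
            for i, series in enumerate(replicates)
        ]
        est = aggregate_replicates(per_rep)
        rows.append(
            {
                "system": name,
                "p_bound": round(est.p_bound, 2),
                "sd_bound": round(est.sd_bound, 2),
                "p_unbound": round(est.p_unbound, 2),
                "sd_unbound": round(est.sd_unbound, 2),
                "n_replicates": est.n_replicates,
            }
        )
    return pd.DataFrame(rows)
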