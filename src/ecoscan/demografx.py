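"""X-chromosome rate scaling and X/autosome effective-size trajectories.

With a male-to-female mutation rate ratio alpha, the neutral X rate is
``mu_X = mu_A * 2(2 + alpha) / (3(1 + alpha))`` — X chromosomes spend 1/3
of their history in males versus 1/2 for autosomes. The attainable ratio
``mu_X/mu_A`` is the open interval (2/3, 4/3); inverting a ratio outside it
is reported as infeasible rather than forced. Ne trajectories are stepwise
constant (the atomic-interval form sequential-coalescent output is drawn
in), evaluated right-continuously.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

RATIO_LOWER = 2.0 / 3.0  # alpha -> infinity
RATIO_UPPER = 4.0 / 3.0  # alpha -> 0
NEUTRAL_X_AUTOSOME_RATIO = 0.75


@dataclass
class MuScalingParams:
    mu_a: float  # autosomal rate per site per generation
    alpha: float  # male-to-female mutation rate ratio

    def __post_init__(self):
        if self.mu_a <= 0:
            raise ValueError("mu_a must be positive")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")


def scale_mu_x(params: MuScalingParams) -> float:
    """Neutral X-chromosome mutation rate implied by alpha."""
    a = params.alpha
    return params.mu_a * 2.0 * (2.0 + a) / (3.0 * (1.0 + a))


def invert_alpha(ratio: float):
    """Solve the X scaling formula for alpha, or "infeasible" outside (2/3, 4/3).

    ``ratio = mu_X / mu_A``. The formula's range is the open interval
    (2/3, 4/3); a ratio outside it cannot come from any positive alpha
    (the "biologically unrealistic" regime).
    """
    ratio = float(ratio)
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    if not (RATIO_LOWER < ratio < RATIO_UPPER):
        return "infeasible"
    return (4.0 - 3.0 * ratio) / (3.0 * ratio - 2.0)


@dataclass
class NeTrajectory:
    """Stepwise-constant effective-size history for one marker class."""

    steps: list  # ordered (time_start_years, Ne)
    marker: str = "autosome"
    mu_used: float | None = None
    generation_time_years: float | None = None

    def __post_init__(self):
        times = [t for t, _ in self.steps]
        if not self.steps:
            raise ValueError("trajectory needs at least one step")
        if times != sorted(times) or len(set(times)) != len(times):
            raise ValueError("step times must be strictly increasing")
        if any(ne <= 0 for _, ne in self.steps):
            raise ValueError("Ne must be positive")

    @property
    def times(self) -> np.ndarray:
        return np.array([t for t, _ in self.steps], dtype=float)

    @property
    def sizes(self) -> np.ndarray:
        return np.array([n for _, n in self.steps], dtype=float)

    def at(self, grid) -> np.ndarray:
        """Right-continuous step evaluation at the grid times."""
        grid = np.asarray(grid, dtype=float)
        if np.any(grid < self.times[0]):
            raise ValueError("grid point precedes trajectory span")
        idx = np.searchsorted(self.times, grid, side="right") - 1
        return self.sizes[idx]

    @classmethod
    def from_table(cls, df: pd.DataFrame, marker: str = "autosome", **kw) -> "NeTrajectory":
        t_col, ne_col = df.columns[:2]
        return cls(steps=list(zip(df[t_col].astype(float), df[ne_col].astype(float))), marker=marker, **kw)


def ne_ratio_trajectory(auto: NeTrajectory, x: NeTrajectory, grid, threshold: float = NEUTRAL_X_AUTOSOME_RATIO):
    """NeX/NeA ratio series on a time grid plus a small summary.

    The summary reports min and max ratio and the grid times at which the
    series crosses ``threshold`` (default 3/4, the neutral X/autosome
    expectation under equal breeding sex ratios).
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty grid")
    ratio = x.at(grid) / auto.at(grid)
    series = pd.DataFrame({"time": grid, "ne_x": x.at(grid), "ne_a": auto.at(grid), "ratio": ratio})
    above = ratio > threshold
    crossings = grid[1:][above[1:] != above[:-1]]
    summary = {
        "min_ratio": float(ratio.min()),
        "max_ratio": float(ratio.max()),
        "threshold": float(threshold),
        "crossing_times": [float(t) for t in crossings],
    }
    return series, summary
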