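"""Membrane-deflection regime over groove width and substrate angle.

Composes the mid-span deflection relation d/L = (q/24EI)·L³/16 + θ_M/4
with the piecewise θ_M(θ_S) relation to map the predicted deflection over
the (L, θ_S) plane, and extracts the d/L = level contour in closed form.

Three numbers summarise the diagram at the default level 0.05:

* the critical groove width L* = [16·level/(q/24EI)]^(1/3) above which
  bending is predicted at every substrate angle (≈1.9 µm at the fitted
  ratio 1.2e17 m⁻³);
* the low critical substrate angle where, as L → 0, the θ_M/4 term alone
  reaches the level on the linear branch (≈13.6° at the fitted constants);
* the high critical substrate angle where the exponential decay of θ_M
  brings d/L back under the level (≈49° at the fitted constants).

Between the two critical angles bending is predicted at every width
(zero-width contour); outside them the contour sits near L*.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .angles import AngleRelationParameters, predict_theta_M
from .beam import normalized_max_deflection

__all__ = [
    "PhaseDiagramResult",
    "dl_at",
    "critical_width",
    "critical_angle_small_width",
    "critical_angle_large_width",
    "threshold_curve",
    "compute_grid",
]

DEFAULT_LEVEL = 0.05


def _effective_theta_M_deg(
    theta_S, angle_params: AngleRelationParameters, hard_step: bool
) -> np.ndarray:
    """θ_M (degrees) from θ_S, optionally zeroed beyond the knee.

    The printed decay branch is the default; ``hard_step`` instead drops
    θ_M to 0 for θ_S > b, matching the verbal description of an abrupt
    return to the non-bending regime at the knee.
    """
    theta_S = np.asarray(theta_S, dtype=float)
    tm = np.asarray(predict_theta_M(theta_S, angle_params), dtype=float)
    if hard_step:
        tm = np.where(theta_S > angle_params.b, 0.0, tm)
    return tm


def dl_at(
    L: float | np.ndarray,
    theta_S: float | np.ndarray,
    angle_params: AngleRelationParameters,
    load_ratio: float,
    *,
    hard_step: bool = False,
) -> float | np.ndarray:
    """Predicted d/L at groove width L (m) and substrate angle θ_S (deg)."""
    L = np.asarray(L, dtype=float)
    if np.any(L <= 0):
        raise ValueError("L must be > 0")
    if load_ratio < 0:
        raise ValueError("load_ratio must be >= 0")
    tm_rad = np.radians(_effective_theta_M_deg(theta_S, angle_params, hard_step))
    out = load_ratio * L**3 / 16.0 + tm_rad / 4.0
    return float(out) if np.ndim(out) == 0 else out


def critical_width(
    load_ratio: float, level: float = DEFAULT_LEVEL, theta_M: float = 0.0
) -> float:
    """Groove width L* (m) at which d/L reaches ``level`` for fixed θ_M (rad).

    Closed-form inversion of the cubic load term:
    L* = [16·(level − θ_M/4)/load_ratio]^(1/3).  Returns 0 when the angle
    term alone meets the level (bending at all widths).
    """
    if load_ratio <= 0:
        raise ValueError("load_ratio must be > 0")
    if theta_M < 0:
        raise ValueError("theta_M must be >= 0")
    excess = level - theta_M / 4.0
    if excess <= 0:
        return 0.0
    return float((16.0 * excess / load_ratio) ** (1.0 / 3.0))


def critical_angle_small_width(
    angle_params: AngleRelationParameters, level: float = DEFAULT_LEVEL
) -> float:
    """Substrate angle (deg) where bending begins in the L → 0 limit.

    As L → 0 the deflection reduces to θ_M/4 (radians); on the linear
    branch θ_M = a·θ_S, so the contour reaches zero width at
    θ_S = degrees(4·level)/a.

    Raises
    ------
    ValueError
        If 4·level exceeds the relation's peak radians(a·b) — the contour
        then never reaches zero width at any substrate angle.
    """
    if level <= 0:
        raise ValueError("level must be > 0")
    peak_rad = np.radians(angle_params.a * angle_params.b)
    if 4.0 * level > peak_rad:
        raise ValueError(
            f"level {level} is never reached at zero width: "
            f"4*level={4 * level:.4f} rad exceeds the relation peak "
            f"{peak_rad:.4f} rad"
        )
    return float(np.degrees(4.0 * level) / angle_params.a)


def critical_angle_large_width(
    angle_params: AngleRelationParameters, level: float = DEFAULT_LEVEL
) -> float:
    """Substrate angle (deg) where the decaying branch exits the level.

    On the decay branch θ_M = a·b·exp(−(θ_S−b)/c); solving
    radians(θ_M)/4 = level gives θ_S = b + c·ln(radians(a·b)/(4·level)).
    Requires ``c`` identified (finite).
    """
    if level <= 0:
        raise ValueError("level must be > 0")
    if not np.isfinite(angle_params.c):
        raise ValueError("decay scale c is not identified")
    peak_rad = np.radians(angle_params.a * angle_params.b)
    if 4.0 * level > peak_rad:
        raise ValueError("level is never reached: no high critical angle")
    return float(
        angle_params.b + angle_params.c * np.log(peak_rad / (4.0 * level))
    )


def threshold_curve(
    angle_params: AngleRelationParameters,
    load_ratio: float,
    level: float = DEFAULT_LEVEL,
    theta_S_grid: np.ndarray | None = None,
    *,
    hard_step: bool = False,
) -> np.ndarray:
    """Critical width L*(θ_S) (m) along a grid of substrate angles.

    Zero entries mean the angle term alone reaches the level: bending is
    predicted at all groove widths for that substrate angle.
    """
    if theta_S_grid is None:
        theta_S_grid = np.linspace(0.0, 80.0, 201)
    theta_S_grid = np.asarray(theta_S_grid, dtype=float)
    if theta_S_grid.size == 0:
        raise ValueError("theta_S_grid must be non-empty")
    tm_rad = np.radians(_effective_theta_M_deg(theta_S_grid, angle_params, hard_step))
    return np.array(
        [critical_width(load_ratio, level, tm) for tm in tm_rad]
    )


@dataclass(frozen=True)
class PhaseDiagramResult:
    """d/L over an (L, θ_S) grid with the extracted threshold contour.

    ``dL_values[i, j]`` is the predicted d/L at ``L_grid[i]``,
    ``theta_S_grid[j]``; ``threshold_curve[j]`` is the critical width at
    ``theta_S_grid[j]`` (0 = bending at all widths).
    """

    L_grid: np.ndarray
    theta_S_grid: np.ndarray
    dL_values: np.ndarray
    level: float
    threshold_curve: np.ndarray

    def bending_regime(self) -> np.ndarray:
        """Boolean grid: True where d/L >= level (bending predicted)."""
        return self.dL_values >= self.level

    def summary(
        self, angle_params: AngleRelationParameters, load_ratio: float
    ) -> dict:
        out = {
            "level": self.level,
            "critical_width_m": critical_width(load_ratio, self.level),
            "critical_angle_low_deg": None,
            "critical_angle_high_deg": None,
        }
        try:
            out["critical_angle_low_deg"] = critical_angle_small_width(
                angle_params, self.level
            )
            out["critical_angle_high_deg"] = critical_angle_large_width(
                angle_params, self.level
            )
        except ValueError:
            pass
        return out

    def to_frame(self):
        """Long-format table (L_m, theta_S_deg, dL), one row per node."""
        import pandas as pd

        Lm, Ts = np.meshgrid(self.L_grid, self.theta_S_grid, indexing="ij")
        return pd.DataFrame(
            {
                "L_m": Lm.ravel(),
                "theta_S_deg": Ts.ravel(),
                "dL": self.dL_values.ravel(),
            }
        )


def compute_grid(
    angle_params: AngleRelationParameters,
    load_ratio: float,
    level: float = DEFAULT_LEVEL,
    L_grid: np.ndarray | None = None,
    theta_S_grid: np.ndarray | None = None,
    *,
    hard_step: bool = False,
) -> PhaseDiagramResult:
    """Fill the (L, θ_S) deflection grid and attach the threshold contour."""
    if L_grid is None:
        L_grid = np.linspace(0.1e-6, 4e-6, 200)
    if theta_S_grid is None:
        theta_S_grid = np.linspace(0.0, 80.0, 200)
    L_grid = np.asarray(L_grid, dtype=float)
    theta_S_grid = np.asarray(theta_S_grid, dtype=float)
    for name, g in (("L_grid", L_grid), ("theta_S_grid", theta_S_grid)):
        if g.size == 0:
            raise ValueError(f"{name} must be non-empty")
        if g.size > 1 and np.any(np.diff(g) <= 0):
            raise ValueError(f"{name} must be strictly increasing")
    if np.any(L_grid <= 0):
        raise ValueError("L_grid must be positive")

    dL = dl_at(
        L_grid[:, None], theta_S_grid[None, :], angle_params, load_ratio,
        hard_step=hard_step,
    )
    curve = threshold_curve(
        angle_params, load_ratio, level, theta_S_grid, hard_step=hard_step
    )
    return PhaseDiagramResult(
        L_grid=L_grid,
        theta_S_grid=theta_S_grid,
        dL_values=np.atleast_2d(dL),
        level=level,
        threshold_curve=curve,
    )


def plot_phase_diagram(result: PhaseDiagramResult, ax=None):
    """Heatmap of d/L over (θ_S, L) with the threshold contour overlaid."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4.5))
    Ts, Lm = np.meshgrid(result.theta_S_grid, result.L_grid * 1e6)
    pcm = ax.pcolormesh(Ts, Lm, result.dL_values, shading="auto", cmap="viridis")
    ax.figure.colorbar(pcm, ax=ax, label="d/L")
    ax.plot(
        result.theta_S_grid,
        result.threshold_curve * 1e6,
        color="black",
        lw=2,
        label=f"d/L = {result.level}",
    )
    ax.set_xlabel("substrate bending angle θ_S (deg)")
    ax.set_ylabel("groove width L (µm)")
    ax.set_ylim(result.L_grid.min() * 1e6, result.L_grid.max() * 1e6)
    ax.legend(loc="upper right")
    return ax
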