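"""Piecewise relation between membrane and substrate bending angles.

The membrane bending angle theta_M tracks the substrate bending angle
theta_S (the inherent fabrication slope at a ridge-top edge) in two
regimes.  Below a knee angle ``b`` adhesion wins over the membrane's
bending stiffness and theta_M rises linearly; above ``b`` the substrate is
too steep for adhesion to hold the membrane down and theta_M decays
exponentially back towards zero:

    theta_M = a * theta_S                       for theta_S <= b
    theta_M = a * b * exp(-(theta_S - b) / c)   for theta_S >  b

All three constants are fitted by least squares; the two branches meet
continuously at theta_S = b (both equal a*b).  Angles are handled in
degrees throughout this module — the fitted constants are degree-valued —
and converted to radians only where they enter the beam model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "AngleRelationParameters",
    "AngleRelationFit",
    "PAPER_ANGLE_PARAMS",
    "predict_theta_M",
    "fit_angle_relation",
]


@dataclass(frozen=True)
class AngleRelationParameters:
    """Constants of the piecewise linear/exponential angle relation.

    a : linear slope (dimensionless); b : regime-change (knee) angle in
    degrees; c : exponential decay scale in degrees.  All strictly
    positive; ``c`` may be NaN when a fit could not identify the decay
    scale (no data beyond the knee).  The relation peaks at theta_S = b
    with value a*b.
    """

    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        c_ok = self.c > 0 or np.isnan(self.c)
        if not (self.a > 0 and self.b > 0 and c_ok):
            raise ValueError(
                f"a, b, c must all be > 0, got ({self.a}, {self.b}, {self.c})"
            )

    def to_dict(self) -> dict:
        return {"a": self.a, "b_deg": self.b, "c_deg": self.c}

    @classmethod
    def from_dict(cls, d: dict) -> "AngleRelationParameters":
        return cls(a=d["a"], b=d.get("b_deg", d.get("b")), c=d.get("c_deg", d.get("c")))


#: Constants fitted to the original bending dataset.
PAPER_ANGLE_PARAMS = AngleRelationParameters(a=0.8433, b=44.0, c=4.397)


def predict_theta_M(
    theta_S: float | np.ndarray, params: AngleRelationParameters
) -> float | np.ndarray:
    """Predicted membrane bending angle (degrees) at substrate angle(s).

    Linear branch ``a*theta_S`` up to and including the knee ``b``;
    exponential decay ``a*b*exp(-(theta_S-b)/c)`` beyond it.  Points
    exactly at the knee fall on the linear branch (the branches agree
    there, so the choice is residual-neutral).
    """
    theta_S = np.asarray(theta_S, dtype=float)
    if np.any(theta_S < 0):
        raise ValueError("theta_S must be >= 0")
    linear = params.a * theta_S
    # exponent clipped at 0: positive arguments only arise on the ts <= b
    # side, where np.where discards the decay value anyway
    decay = params.a * params.b * np.exp(
        np.minimum(-(theta_S - params.b) / params.c, 0.0)
    )
    out = np.where(theta_S <= params.b, linear, decay)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class AngleRelationFit:
    """Fitted angle-relation constants plus least-squares diagnostics."""

    params: AngleRelationParameters
    rss: float
    n_pairs: int
    c_identifiable: bool
    n_starts: int = field(default=0, compare=False)

    def to_dict(self) -> dict:
        return {
            "a": self.params.a,
            "b_deg": self.params.b,
            "c_deg": self.params.c,
            "rss": self.rss,
            "n_pairs": self.n_pairs,
            "c_identifiable": self.c_identifiable,
        }


# Candidate knee angles used to multi-start the nonlinear fit: the RSS is
# non-smooth in b, so a single local solve can stall in the wrong regime.
DEFAULT_KNEE_GRID = tuple(float(b) for b in range(10, 75, 5))


def fit_angle_relation(
    pairs: "Iterable[tuple[float, float]] | Sequence",
    *,
    knee_grid: Sequence[float] = DEFAULT_KNEE_GRID,
    xtol: float = 1e-12,
    ftol: float = 1e-12,
) -> AngleRelationFit:
    """Fit (a, b, c) to (theta_S, theta_M) pairs (degrees) by least squares.

    Joint nonlinear least squares over all three constants, multi-started
    from a grid of candidate knee angles; at each start ``a`` is profiled
    by a through-origin linear fit on the sub-knee points.  The lowest-RSS
    solution wins; the procedure is deterministic for fixed input.

    If the best fit places no data beyond its knee, the decay scale ``c``
    is not constrained by the data and the result is flagged
    ``c_identifiable=False`` (``a`` and ``b`` still come from the linear
    branch).

    Raises
    ------
    ValueError
        If fewer than 4 pairs are supplied.
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be (theta_S, theta_M) two-column data")
    if arr.shape[0] < 4:
        raise ValueError(f"need at least 4 pairs to fit, got {arr.shape[0]}")
    ts, tm = arr[:, 0], arr[:, 1]
    if np.any(ts < 0):
        raise ValueError("theta_S must be >= 0")

    def residuals(p: np.ndarray) -> np.ndarray:
        a, b, c = p
        decay = a * b * np.exp(np.minimum(-(ts - b) / c, 0.0))
        pred = np.where(ts <= b, a * ts, decay)
        return pred - tm

    ts_max = float(ts.max())
    best = None
    n_starts = 0
    for b0 in knee_grid:
        sub = ts <= b0
        if sub.sum() >= 2 and float(np.dot(ts[sub], ts[sub])) > 0:
            a0 = float(np.dot(ts[sub], tm[sub]) / np.dot(ts[sub], ts[sub]))
        else:
            a0 = 1.0
        a0 = max(a0, 1e-3)
        for c0 in (2.0, 5.0, 15.0):
            n_starts += 1
            try:
                sol = least_squares(
                    residuals,
                    x0=[a0, b0, c0],
                    bounds=([1e-6, 1e-6, 1e-6], [np.inf, np.inf, np.inf]),
                    xtol=xtol,
                    ftol=ftol,
                    gtol=1e-12,
                )
            except Exception:
                continue
            if best is None or sol.cost < best.cost - 1e-15:
                best = sol
    if best is None:
        raise RuntimeError("angle-relation fit failed from every start")

    a, b, c = (float(v) for v in best.x)
    beyond = int(np.sum(ts > b))
    c_identifiable = beyond >= 1 and b < ts_max
    if not c_identifiable:
        # Decay scale unconstrained: report the linear-branch fit cleanly.
        a_lin = float(np.dot(ts, tm) / np.dot(ts, ts)) if np.dot(ts, ts) > 0 else a
        a, b = a_lin, ts_max
        rss = float(np.sum((a * ts - tm) ** 2))
        params = AngleRelationParameters(a=a, b=b, c=float("nan"))
    else:
        rss = float(2.0 * best.cost)
        params = AngleRelationParameters(a=a, b=b, c=c)

    return AngleRelationFit(
        params=params,
        rss=rss,
        n_pairs=arr.shape[0],
        c_identifiable=c_identifiable,
        n_starts=n_starts,
    )
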