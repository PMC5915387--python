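"""Closed-form membrane-deflection model adapted from beam-bending theory.

A section of basal membrane spanning a grating groove of width ``L`` is
treated as a linear elastic beam, freely supported on the adjacent ridge
tops at its two ends A and B, pushed into the groove by a uniformly
distributed load ``q`` (cytosolic pressure / actin polymerisation acting on
the membrane).  ``EI`` is the flexural rigidity — the couple needed to bend
the membrane to unit curvature, the beam-theory analogue of the membrane
bending modulus.  Surface tension is neglected.

With end tangent angles ``theta_A`` and ``theta_B`` (radians, measured from
the straight zero-deflection line AB) the downward displacement at position
``x`` along the span is

    v(x) = (q x^2 / 24EI)(L^2 - 2Lx + x^2)
         + (theta_A / L^2)(L^2 x - 2Lx^2 + x^3)
         + (theta_B / L^2)(L x^2 - x^3)

returned here as a downward-positive magnitude so that measured deflections
``d`` are non-negative.  For the symmetric case theta_A = theta_B = theta_M
the maximum sits at mid-span and the normalised maximum deflection is

    d/L = (q/24EI) (L^3/16) + theta_M/4

The combined ratio q/24EI (units m^-3) is the single parameter the
deflection data constrain, and is what :func:`fit_load_ratio` estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "BeamParameters",
    "DeflectionSpec",
    "LoadRatioFit",
    "deflection_profile",
    "normalized_max_deflection",
    "strain_energy",
    "estimate_q_from_pressure",
    "estimate_EI_from_energy",
    "fit_load_ratio",
]


@dataclass(frozen=True)
class BeamParameters:
    """Load intensity, flexural rigidity and/or their combined ratio.

    Parameters
    ----------
    q : float or None
        Distributed load intensity (N/m), >= 0.
    EI : float or None
        Flexural rigidity (N·m²), > 0.
    load_ratio : float or None
        q/(24·EI) in m⁻³.  Derived from ``q`` and ``EI`` when both are
        given; may also be supplied alone, straight from a fit.
    """

    q: float | None = None
    EI: float | None = None
    load_ratio: float | None = None

    def __post_init__(self) -> None:
        if self.q is not None and self.q < 0:
            raise ValueError(f"q must be >= 0, got {self.q}")
        if self.EI is not None and self.EI <= 0:
            raise ValueError(f"EI must be > 0, got {self.EI}")
        if self.q is not None and self.EI is not None:
            derived = self.q / (24.0 * self.EI)
            if self.load_ratio is None:
                object.__setattr__(self, "load_ratio", derived)
            elif not np.isclose(self.load_ratio, derived, rtol=1e-12, atol=0.0):
                raise ValueError(
                    f"inconsistent parameters: load_ratio={self.load_ratio} "
                    f"but q/(24 EI)={derived}"
                )
        if self.load_ratio is None:
            raise ValueError("need either load_ratio or both q and EI")
        if self.load_ratio < 0:
            raise ValueError(f"load_ratio must be >= 0, got {self.load_ratio}")

    def to_dict(self) -> dict:
        return {
            "q_N_per_m": self.q,
            "EI_Nm2": self.EI,
            "load_ratio_per_m3": self.load_ratio,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BeamParameters":
        return cls(
            q=d.get("q_N_per_m"),
            EI=d.get("EI_Nm2"),
            load_ratio=d.get("load_ratio_per_m3"),
        )


@dataclass(frozen=True)
class DeflectionSpec:
    """Span and end rotations for one groove crossing.

    ``L`` in metres; ``theta_A`` and ``theta_B`` are the end tangent angles
    in radians (angles from the zero-deflection line AB).
    """

    L: float
    theta_A: float = 0.0
    theta_B: float = 0.0

    def __post_init__(self) -> None:
        if self.L <= 0:
            raise ValueError(f"span L must be > 0, got {self.L}")
        if self.theta_A < 0 or self.theta_B < 0:
            raise ValueError("end rotations must be >= 0")


def deflection_profile(
    x: float | np.ndarray, spec: DeflectionSpec, params: BeamParameters
) -> float | np.ndarray:
    """Downward displacement magnitude v(x) along the span (metres).

    Evaluates the closed-form displacement polynomial for a uniformly
    loaded span with prescribed end rotations; positive values point into
    the groove.  ``params`` must carry ``q`` and ``EI`` explicitly so the
    profile is tied to stated mechanics, not just a fitted ratio.

    Raises
    ------
    ValueError
        If any ``x`` lies outside [0, L] or q/EI are missing.
    """
    if params.q is None or params.EI is None:
        raise ValueError("deflection_profile requires explicit q and EI")
    x = np.asarray(x, dtype=float)
    L = spec.L
    if np.any(x < 0) or np.any(x > L):
        raise ValueError(f"x must lie within [0, {L}]")
    load_term = (params.q * x**2 / (24.0 * params.EI)) * (L**2 - 2 * L * x + x**2)
    a_term = (spec.theta_A / L**2) * (L**2 * x - 2 * L * x**2 + x**3)
    b_term = (spec.theta_B / L**2) * (L * x**2 - x**3)
    v = load_term + a_term + b_term
    return float(v) if v.ndim == 0 else v


def normalized_max_deflection(
    L: float, load_ratio: float, theta_M: float
) -> float:
    """Normalised maximum deflection d/L at mid-span (dimensionless).

    ``theta_M`` is the (symmetric) membrane bending angle in **radians**;
    ``load_ratio`` is q/24EI in m⁻³.
    """
    if L <= 0:
        raise ValueError(f"span L must be > 0, got {L}")
    if load_ratio < 0:
        raise ValueError(f"load_ratio must be >= 0, got {load_ratio}")
    if theta_M < 0:
        raise ValueError(f"theta_M must be >= 0, got {theta_M}")
    return load_ratio * L**3 / 16.0 + theta_M / 4.0


def strain_energy(q: float, L: float, EI: float) -> float:
    """Strain energy U = q²L⁵/(240·EI) of the uniformly loaded span (J)."""
    if L <= 0:
        raise ValueError(f"span L must be > 0, got {L}")
    if EI <= 0:
        raise ValueError(f"EI must be > 0, got {EI}")
    if q < 0:
        raise ValueError(f"q must be >= 0, got {q}")
    return q**2 * L**5 / (240.0 * EI)


def estimate_q_from_pressure(pressure: float, cell_length: float) -> float:
    """Line load q (N/m) from cytosolic pressure (Pa) over a cell length (m).

    A uniform pressure acting across the load-bearing length of an
    elongated cell gives a force per unit length of membrane span equal to
    pressure × length (e.g. 300 Pa over 100 µm → 0.03 N/m).
    """
    if cell_length <= 0:
        raise ValueError(f"cell_length must be > 0, got {cell_length}")
    if pressure < 0:
        raise ValueError(f"pressure must be >= 0, got {pressure}")
    return pressure * cell_length


def estimate_EI_from_energy(q: float, L: float, U: float) -> float:
    """Flexural rigidity EI (N·m²) from the energy stored at unit curvature.

    Algebraic inversion of :func:`strain_energy` for EI: q²L⁵/(240·U).
    ``U`` is the bending energy (J) taken as stored in the loaded span.
    """
    if U <= 0:
        raise ValueError(f"U must be > 0, got {U}")
    if q <= 0:
        raise ValueError(f"q must be > 0, got {q}")
    if L <= 0:
        raise ValueError(f"L must be > 0, got {L}")
    return q**2 * L**5 / (240.0 * U)


@dataclass(frozen=True)
class LoadRatioFit:
    """Through-origin least-squares estimate of q/24EI with diagnostics."""

    load_ratio: float
    n_records: int
    rss: float
    r_squared: float
    negative_slope: bool = False
    intercept_fit: dict | None = field(default=None, compare=False)

    def to_dict(self) -> dict:
        return {
            "load_ratio_per_m3": self.load_ratio,
            "n_records": self.n_records,
            "rss": self.rss,
            "r_squared": self.r_squared,
        }


def fit_load_ratio(
    records: "Iterable | Sequence",
    *,
    with_intercept_diagnostic: bool = False,
) -> LoadRatioFit:
    """Estimate the load ratio q/24EI from groove measurements.

    Rearranging the mid-span deflection relation, each record contributes a
    point on the through-origin line

        (d/L - theta_M/4) = (q/24EI) · (L³/16)

    with theta_M converted to radians.  The slope is the ordinary
    least-squares solution with no intercept (the model has no constant
    term).  ``records`` may be any iterable of objects (or mapping rows)
    with attributes/keys ``L``/``L_m``, ``d``/``d_m`` and
    ``theta_M``/``theta_M_deg`` (degrees).

    A negative fitted slope is reported in the diagnostics, never clamped.
    Set ``with_intercept_diagnostic`` to also report an (unused) fit with a
    free intercept, as a model-structure check.
    """
    L_vals, d_vals, th_vals = [], [], []
    for rec in records:
        L = _get(rec, "L", "L_m")
        d = _get(rec, "d", "d_m")
        th = _get(rec, "theta_M", "theta_M_deg")
        L_vals.append(float(L))
        d_vals.append(float(d))
        th_vals.append(float(th))
    L_arr = np.asarray(L_vals)
    d_arr = np.asarray(d_vals)
    th_rad = np.radians(np.asarray(th_vals))
    n = L_arr.size
    if n < 2:
        raise ValueError(f"need at least 2 records, got {n}")
    if np.any(L_arr <= 0) or np.any(d_arr < 0):
        raise ValueError("records must have L > 0 and d >= 0")

    x = L_arr**3 / 16.0
    y = d_arr / L_arr - th_rad / 4.0
    sxx = float(np.dot(x, x))
    if sxx == 0.0 or (np.allclose(L_arr, L_arr[0], rtol=1e-15, atol=0.0)
                      and np.unique(x).size < 2):
        raise ValueError("singular fit: all spans identical, slope not identifiable")
    slope = float(np.dot(x, y) / sxx)
    resid = y - slope * x
    rss = float(np.dot(resid, resid))
    tss = float(np.dot(y, y))  # uncentred: model has no intercept
    r2 = 1.0 - rss / tss if tss > 0 else float("nan")

    intercept_fit = None
    if with_intercept_diagnostic:
        # centred closed form: x spans ~1e-19 m^3 so a raw design matrix
        # with an intercept column is numerically singular
        xbar, ybar = float(x.mean()), float(y.mean())
        var = float(np.sum((x - xbar) ** 2))
        m = float(np.sum((x - xbar) * (y - ybar)) / var) if var > 0 else float("nan")
        b = ybar - m * xbar
        intercept_fit = {
            "slope": m,
            "intercept": b,
            "rss": float(np.sum((y - m * x - b) ** 2)),
        }

    return LoadRatioFit(
        load_ratio=slope,
        n_records=n,
        rss=rss,
        r_squared=r2,
        negative_slope=slope < 0,
        intercept_fit=intercept_fit,
    )


def _get(rec, *names):
    for name in names:
        if hasattr(rec, name):
            return getattr(rec, name)
        try:
            if name in rec:
                return rec[name]
        except TypeError:
            pass
    raise AttributeError(f"record {rec!r} has none of {names}")
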