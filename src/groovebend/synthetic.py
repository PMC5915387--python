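"""Seeded synthetic data with the statistical structure the analysis assumes.

The original groove-bending measurements are not deposited, so every stage
of the pipeline is exercised on generated data instead: groove records
whose gap widths follow the measured grating dimensions and whose
deflections and angles follow the fitted deflection and angle-relation
models plus configurable Gaussian measurement noise; full cross-section
profiles whose membrane follows the beam deflection curve; and
ellipse-boundary cell outlines for the morphometrics.

All randomness flows from a single seed through ``numpy.random.default_rng``;
identical configuration and seed give identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .angles import AngleRelationParameters, PAPER_ANGLE_PARAMS, predict_theta_M
from .beam import BeamParameters, DeflectionSpec, deflection_profile
from .profiles import CrossSectionProfile, GrooveMeasurement

__all__ = [
    "GratingClass",
    "GeneratorConfig",
    "ALL_GRATING_CLASSES",
    "BENDING_GRATING_CLASSES",
    "generate_groove_records",
    "generate_profile",
    "generate_cell_outlines",
]


@dataclass(frozen=True)
class GratingClass:
    """Measured dimensions (mean ± SD, nm) of one grating geometry.

    The groove gap width is ``spacing − line_width``; its SD pools the two
    measurement SDs in quadrature.
    """

    label: str
    line_width_nm: float
    line_width_sd_nm: float
    spacing_nm: float
    spacing_sd_nm: float
    height_nm: float
    height_sd_nm: float

    def __post_init__(self) -> None:
        vals = (
            self.line_width_nm,
            self.line_width_sd_nm,
            self.spacing_nm,
            self.spacing_sd_nm,
            self.height_nm,
            self.height_sd_nm,
        )
        if any(v <= 0 for v in vals):
            raise ValueError("all means and SDs must be > 0")
        if self.spacing_nm <= self.line_width_nm:
            raise ValueError("spacing must exceed line width (positive gap)")

    @property
    def gap_nm(self) -> float:
        return self.spacing_nm - self.line_width_nm

    @property
    def gap_sd_nm(self) -> float:
        return float(np.hypot(self.line_width_sd_nm, self.spacing_sd_nm))


#: Measured grating dimensions of the study substrates (AFM/SEM, nm).
ALL_GRATING_CLASSES: tuple[GratingClass, ...] = (
    GratingClass("350nm", 339.0, 7.0, 688.0, 22.0, 345.0, 13.0),
    GratingClass("500nm", 490.0, 20.0, 966.0, 33.0, 354.0, 22.0),
    GratingClass("1um", 981.0, 50.0, 1974.0, 52.0, 341.0, 24.0),
    GratingClass("2um", 1983.0, 65.0, 3906.0, 71.0, 365.0, 26.0),
    GratingClass("10um", 9965.0, 33.0, 19422.0, 307.0, 355.0, 26.0),
)

#: The classes the membrane-bending dataset covers (the 10 µm gratings are
#: far beyond the deflection model's regime and are excluded from fits).
BENDING_GRATING_CLASSES: tuple[GratingClass, ...] = ALL_GRATING_CLASSES[:4]


@dataclass(frozen=True)
class GeneratorConfig:
    """Ground truth and noise settings for the record generator.

    Defaults are the fitted study values: load ratio q/24EI = 1.2e17 m⁻³,
    angle relation (a, b, c) = (0.8433, 44°, 4.397°); noise SDs are the
    assumed measurement scatter (0.01 on d/L, 2° on angles).  ``n_per_class``
    defaults to 112 = 14 cells × 8 membrane-ridge pairs.
    """

    load_ratio: float = 1.2e17
    angle_params: AngleRelationParameters = field(default_factory=lambda: PAPER_ANGLE_PARAMS)
    sigma_dL: float = 0.01
    sigma_angle_deg: float = 2.0
    n_per_class: int = 112
    theta_S_range: tuple[float, float] = (0.0, 70.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_dL < 0 or self.sigma_angle_deg < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if self.load_ratio < 0:
            raise ValueError("load_ratio must be >= 0")
        lo, hi = self.theta_S_range
        if not (0 <= lo < hi):
            raise ValueError("theta_S_range must satisfy 0 <= lo < hi")

    def with_seed(self, seed: int) -> "GeneratorConfig":
        return replace(self, seed=seed)


_MAX_REDRAWS = 1000


def _truncated_normal(rng, mean, sd, low, size):
    """Normal draws redrawn until above ``low`` (rejection sampling)."""
    out = rng.normal(mean, sd, size=size)
    for _ in range(_MAX_REDRAWS):
        bad = out <= low if np.isscalar(low) else out <= low
        if not np.any(bad):
            return out
        out = np.where(bad, rng.normal(mean, sd, size=size), out)
    raise RuntimeError("truncated sampling exhausted redraws; check mean/SD")


def generate_groove_records(
    config: GeneratorConfig,
    classes: tuple[GratingClass, ...] | None = None,
) -> list[GrooveMeasurement]:
    """Draw per-groove measurement records from the composed model.

    Per record: gap L ~ Normal(class gap mean, pooled SD) truncated
    positive; θ_S ~ Uniform over ``theta_S_range``; θ_M = piecewise
    relation of θ_S plus Gaussian angle noise (floored at 0); d/L = beam
    relation evaluated at the record's own θ_M plus Gaussian noise,
    truncated at 0.
    """
    if classes is None:
        classes = BENDING_GRATING_CLASSES
    rng = np.random.default_rng(config.seed)
    lo, hi = config.theta_S_range
    records: list[GrooveMeasurement] = []
    for cls in classes:
        n = config.n_per_class
        L = _truncated_normal(
            rng, cls.gap_nm * 1e-9, cls.gap_sd_nm * 1e-9, 0.0, n
        )
        theta_S = rng.uniform(lo, hi, size=n)
        theta_M = predict_theta_M(theta_S, config.angle_params)
        if config.sigma_angle_deg > 0:
            theta_M = theta_M + rng.normal(0.0, config.sigma_angle_deg, size=n)
        theta_M = np.clip(theta_M, 0.0, 89.999)
        dl_true = config.load_ratio * L**3 / 16.0 + np.radians(theta_M) / 4.0
        if config.sigma_dL > 0:
            dl = np.maximum(
                _truncated_normal(rng, dl_true, config.sigma_dL, -np.inf, n), 0.0
            )
        else:
            dl = dl_true
        for i in range(n):
            records.append(
                GrooveMeasurement(
                    L=float(L[i]),
                    d=float(dl[i] * L[i]),
                    theta_M=float(theta_M[i]),
                    theta_S=float(theta_S[i]),
                    grating_class=cls.label,
                    groove_id=f"{cls.label}-{i:04d}",
                    endpoint_detail={"seed": config.seed},
                )
            )
    return records


def generate_profile(
    L: float,
    theta_M_deg: float,
    params: BeamParameters,
    *,
    theta_S_deg: float = 0.0,
    n_points: int = 1000,
    ridge_height: float = 350e-9,
    ridge_width: float | None = None,
    jitter_sigma: float = 0.0,
    grating_class: str = "",
    seed: int = 0,
) -> CrossSectionProfile:
    """Synthesize one cross-section profile with a known ground truth.

    The substrate is two ridges of the given height flanking a gap of
    width ``L``; each ridge top is a straight facet descending toward the
    gap at the substrate bending angle θ_S.  The membrane rests on the
    ridge tops and crosses the gap along the beam deflection curve with
    symmetric end rotations, where the end-slope coefficient is
    tan(θ_M) so the geometric tangent angle at the contacts equals the
    requested θ_M (the small-angle identification tan θ ≈ θ made exact).
    Optional Gaussian jitter perturbs membrane y.

    The true (L, d, θ_M, θ_S) are stored in the profile metadata.  If the
    deflection exceeds the ridge height the membrane is clipped at the
    groove floor and the profile flagged ``clipped=True``.
    """
    if n_points < 50:
        raise ValueError("n_points must be >= 50")
    if L <= 0 or ridge_height <= 0:
        raise ValueError("L and ridge_height must be > 0")
    if not (0 <= theta_M_deg < 90) or not (0 <= theta_S_deg < 90):
        raise ValueError("angles must lie in [0, 90)")
    rng = np.random.default_rng(seed)
    w = ridge_width if ridge_width is not None else max(L, 5 * ridge_height)
    h = ridge_height
    slope = np.tan(np.radians(theta_S_deg))
    delta = 0.005 * L  # near-vertical groove walls keep x strictly increasing

    # substrate: left ridge top, wall, floor, wall, right ridge top
    n_top = max(50, n_points // 4)
    xl = np.linspace(-w, 0.0, n_top)
    yl = h - xl * slope  # descends toward the gap (y > h away from it)
    xr = np.linspace(L, L + w, n_top)
    yr = h + (xr - L) * slope
    floor_x = np.linspace(delta, L - delta, max(20, n_points // 10))
    sub_x = np.concatenate([xl, floor_x, xr])
    sub_y = np.concatenate([yl, np.zeros_like(floor_x), yr])

    # membrane: contact segments on the ridge tops + deflection curve
    s = np.tan(np.radians(theta_M_deg))  # end tangent slope
    if params.q is not None and params.EI is not None:
        beam = params
    else:
        beam = BeamParameters(q=24.0 * params.load_ratio, EI=1.0)
    spec = DeflectionSpec(L=L, theta_A=s, theta_B=s)
    xc = np.linspace(0.0, L, n_points)
    v = deflection_profile(xc, spec, beam)
    d_true = float(v.max())
    clipped = d_true > h
    y_curve = h - v
    if clipped:
        y_curve = np.maximum(y_curve, 0.0)
    n_contact = max(10, n_points // 10)
    xca = np.linspace(-0.5 * w, 0.0, n_contact, endpoint=False)
    yca = h - xca * slope
    xcb = np.linspace(L, 0.5 * w + L, n_contact + 1)[1:]
    ycb = h + (xcb - L) * slope
    mem_x = np.concatenate([xca, xc, xcb])
    mem_y = np.concatenate([yca, y_curve, ycb])
    if jitter_sigma > 0:
        mem_y = mem_y + rng.normal(0.0, jitter_sigma, size=mem_y.size)

    return CrossSectionProfile(
        membrane=np.column_stack([mem_x, mem_y]),
        substrate=np.column_stack([sub_x, sub_y]),
        grating_class=grating_class,
        metadata={
            "true_L_m": L,
            "true_d_m": min(d_true, h) if clipped else d_true,
            "true_theta_M_deg": theta_M_deg,
            "true_theta_S_deg": theta_S_deg,
            "clipped": clipped,
            "seed": seed,
        },
    )


def generate_cell_outlines(
    n: int,
    elongation,
    orientation_deg,
    *,
    short_axis: float = 20e-6,
    n_vertices: int = 64,
    seed: int = 0,
):
    """Ellipse-boundary cell outlines with known elongation/orientation.

    ``elongation`` and ``orientation_deg`` may be scalars, length-n
    arrays, or callables ``f(rng, n) -> array`` (distributions).  Returns
    ``(polygons, truth)`` where ``truth`` is a dict of the sampled
    ground-truth arrays.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)

    def _sample(spec):
        if callable(spec):
            return np.asarray(spec(rng, n), dtype=float)
        arr = np.asarray(spec, dtype=float)
        return np.full(n, float(arr)) if arr.ndim == 0 else arr

    elong = _sample(elongation)
    orient = _sample(orientation_deg)
    if elong.shape != (n,) or orient.shape != (n,):
        raise ValueError("distribution samples must have length n")
    if np.any(elong < 0):
        raise ValueError("elongation must be >= 0")

    t = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    polygons = []
    for e, ang in zip(elong, orient):
        p = 0.5 * short_axis * (e + 1.0)  # semi-major
        q = 0.5 * short_axis
        rad = np.radians(ang)
        x = p * np.cos(t) * np.cos(rad) - q * np.sin(t) * np.sin(rad)
        y = p * np.cos(t) * np.sin(rad) + q * np.sin(t) * np.cos(rad)
        polygons.append(np.column_stack([x, y]))
    return polygons, {"elongation": elong, "orientation_deg": orient}
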