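"""Geometric measurement of membrane cross-section profiles.

Reproduces, on traced 2D polylines, the measurement procedure applied to
TEM cross-sections of cells on grating substrates: a straight
"zero-deflection" line AB is drawn between the points where the membrane
contacts the tops of two adjacent ridges, and from it four quantities are
read per groove:

* L — gap width, the length of AB;
* d — maximum deflection, the largest perpendicular distance from AB to
  the membrane inside the groove;
* theta_M — membrane bending angle, between AB and the membrane tangent at
  a contact point;
* theta_S — substrate bending angle, between AB and the ridge-top surface
  tangent at a contact point (an inherent fabrication slope, not a
  load-induced deformation).

Angles are measured at both endpoints and averaged; per-endpoint values
are retained.  Also implements the cell-body morphometrics used alongside:
the equimomental ellipse (same area second moments as the cell outline),
the elongation parameter (long/short axis ratio minus one), the alignment
criterion (elongation >= 4 and long axis within 15 degrees of the grating
axis), and the standard segmentation of groove records into four membrane
bending-angle groups at 15/30/45 degrees.

Profiles are continuous polylines in metres, y up; image tracing is out of
scope here (input is assumed pre-traced).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CrossSectionProfile",
    "GrooveMeasurement",
    "MeasurementConfig",
    "NotSpanningError",
    "GeometryError",
    "measure_groove",
    "equimomental_ellipse",
    "elongation_parameter",
    "is_aligned",
    "segment_by_bending_angle",
    "records_to_frame",
    "write_records_csv",
    "read_records_csv",
]

RECORD_COLUMNS = [
    "groove_id",
    "grating_class",
    "L_m",
    "d_m",
    "dL",
    "theta_M_deg",
    "theta_S_deg",
    "theta_M_A_deg",
    "theta_M_B_deg",
    "theta_S_A_deg",
    "theta_S_B_deg",
]


class NotSpanningError(ValueError):
    """The membrane does not span the full groove between two ridge tops."""


class GeometryError(ValueError):
    """The substrate polyline does not expose two ridge tops and a groove."""


@dataclass(frozen=True)
class CrossSectionProfile:
    """Membrane and substrate polylines in a shared 2D frame (metres, y up).

    Both polylines are (n, 2) arrays with strictly increasing x.  The
    membrane may not penetrate the substrate beyond a small contact
    tolerance.
    """

    membrane: np.ndarray
    substrate: np.ndarray
    grating_class: str = ""
    units: str = "m"
    metadata: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        mem = np.asarray(self.membrane, dtype=float)
        sub = np.asarray(self.substrate, dtype=float)
        for name, arr in (("membrane", mem), ("substrate", sub)):
            if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
                raise ValueError(f"{name} must be an (n>=3, 2) polyline")
            if np.any(np.diff(arr[:, 0]) <= 0):
                raise ValueError(f"{name} x-coordinates must be strictly increasing")
        object.__setattr__(self, "membrane", mem)
        object.__setattr__(self, "substrate", sub)

    def to_dict(self) -> dict:
        return {
            "membrane": self.membrane.tolist(),
            "substrate": self.substrate.tolist(),
            "grating_class": self.grating_class,
            "units": self.units,
            **({"metadata": self.metadata} if self.metadata else {}),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_dict(cls, d: dict) -> "CrossSectionProfile":
        return cls(
            membrane=np.asarray(d["membrane"], dtype=float),
            substrate=np.asarray(d["substrate"], dtype=float),
            grating_class=d.get("grating_class", ""),
            units=d.get("units", "m"),
            metadata=d.get("metadata", {}),
        )

    @classmethod
    def from_json(cls, path) -> "CrossSectionProfile":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class GrooveMeasurement:
    """One membrane-over-groove observation.

    ``L`` gap width (m), ``d`` maximum deflection (m), angles in degrees;
    ``endpoint_detail`` holds the per-endpoint (A, B) membrane and
    substrate angles the stored means were averaged from.
    """

    L: float
    d: float
    theta_M: float
    theta_S: float
    grating_class: str = ""
    groove_id: str = ""
    endpoint_detail: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.L <= 0:
            raise ValueError(f"L must be > 0, got {self.L}")
        if self.d < 0:
            raise ValueError(f"d must be >= 0, got {self.d}")
        for name, val in (("theta_M", self.theta_M), ("theta_S", self.theta_S)):
            if not (0.0 <= val < 90.0):
                raise ValueError(f"{name} must lie in [0, 90), got {val}")
        if not np.isfinite(self.d / self.L):
            raise ValueError("d/L must be finite")

    @property
    def dL(self) -> float:
        return self.d / self.L


@dataclass(frozen=True)
class MeasurementConfig:
    """Tunable settings of the groove-measurement procedure.

    contact_tol_frac : vertical contact tolerance as a fraction of ridge
        height (a traced membrane never touches the substrate exactly).
    tangent_window_frac : arc-length window, as a fraction of L, of the
        total-least-squares line fit used for endpoint tangents.
    tangent_min_points : minimum points in a tangent fit.
    tangent_fit_degree : polynomial order of the tangent fit; 3 tracks the
        deflection curve's endpoint slope closely on clean traces, 1 is
        more robust to heavy y-jitter (at the cost of curvature bias).
    """

    contact_tol_frac: float = 0.01
    tangent_window_frac: float = 0.05
    tangent_min_points: int = 3
    tangent_fit_degree: int = 3


# ---------------------------------------------------------------------------
# groove measurement


def _endpoint_tangent_angle(
    pts: np.ndarray,
    origin: np.ndarray,
    ab_unit: np.ndarray,
    normal: np.ndarray,
    scale: float,
    max_degree: int = 3,
) -> float:
    """Unsigned angle (deg) between AB and the curve tangent at ``origin``.

    The window points are mapped into the AB frame (u along the line, w
    perpendicular) and a low-order polynomial w(u) is fitted; the tangent
    is its derivative evaluated at the endpoint u = 0.  Evaluating at the
    endpoint (rather than taking the average window direction) keeps the
    estimate unbiased when the curve's slope varies across the window.
    """
    rel = (pts - origin) / scale  # scale out metric units for conditioning
    u = rel @ ab_unit
    w = rel @ normal
    deg = min(max_degree, len(pts) - 1)
    coeffs = np.polyfit(u, w, deg)
    slope = float(coeffs[-2])  # dw/du at u = 0
    return float(np.degrees(np.arctan(abs(slope))))


def _window_points(
    poly: np.ndarray, idx: int, towards: int, arc_len: float, min_pts: int
) -> np.ndarray:
    """Points of ``poly`` from index ``idx`` walking in direction ``towards``
    (+1 or -1) until the accumulated arc length exceeds ``arc_len``."""
    pts = [poly[idx]]
    dist = 0.0
    j = idx
    while True:
        nxt = j + towards
        if nxt < 0 or nxt >= poly.shape[0]:
            break
        dist += float(np.linalg.norm(poly[nxt] - poly[j]))
        pts.append(poly[nxt])
        j = nxt
        if dist >= arc_len and len(pts) >= min_pts:
            break
    if len(pts) < 2:
        raise GeometryError("too few points for a tangent fit at an endpoint")
    return np.asarray(pts)


def _substrate_height_span(sub: np.ndarray) -> float:
    return float(sub[:, 1].max() - sub[:, 1].min())


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """[start, end) index ranges of each contiguous True run."""
    padded = np.concatenate([[False], mask, [False]])
    edges = np.diff(padded.astype(int))
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    return list(zip(starts, ends))


def measure_groove(
    profile: CrossSectionProfile,
    config: MeasurementConfig | None = None,
    groove_id: str = "",
) -> GrooveMeasurement:
    """Measure (L, d, theta_M, theta_S) from one cross-section profile.

    Contact points A and B are the last membrane vertex in contact with
    the left ridge top and the first in contact with the right ridge top,
    where "in contact" means the vertical clearance to the substrate is at
    most ``contact_tol_frac`` of the ridge height.  The zero-deflection
    line AB then defines L = |AB|, d = the maximum perpendicular distance
    to the membrane on the groove side, and the two angles via local
    total-least-squares tangents (the membrane tangent taken on the groove
    side of each contact point, the substrate tangent on the ridge-top
    side).

    Raises
    ------
    NotSpanningError
        If the membrane is not in contact on both sides of the groove.
    GeometryError
        If the substrate shows no groove between two ridge tops.
    """
    cfg = config or MeasurementConfig()
    mem = profile.membrane
    sub = profile.substrate

    height = _substrate_height_span(sub)
    if height <= 0:
        raise GeometryError("substrate polyline is flat: no ridges detectable")
    tol = cfg.contact_tol_frac * height

    sub_y_at_mem = np.interp(mem[:, 0], sub[:, 0], sub[:, 1])
    clearance = mem[:, 1] - sub_y_at_mem
    if np.any(clearance < -tol):
        raise GeometryError("membrane penetrates the substrate beyond tolerance")

    contact = clearance <= tol
    if not np.any(contact):
        raise NotSpanningError("membrane never contacts the substrate")

    # The groove crossing is the membrane's off-contact run whose
    # substrate beneath dips deepest below the contact line (micro
    # separations on the ridge tops have tolerance-scale depth only).
    candidates = []
    for s, e in _runs(~contact):
        if s == 0 or e == mem.shape[0]:
            continue  # run touches the trace end: contact on one side only
        depth = float(
            np.max(mem[s - 1, 1] - sub_y_at_mem[s:e])
        )  # drop from contact level to substrate inside the run
        candidates.append((depth, s, e))
    if not candidates:
        raise NotSpanningError("membrane does not span the full groove width")
    depth, s, e = max(candidates)
    if depth <= 2.0 * tol:
        raise GeometryError("no groove found beneath the membrane trace")
    ia = s - 1  # A: last contact point before the groove
    ib = e      # B: first contact point after the groove

    A, B = mem[ia], mem[ib]
    ab = B - A
    L = float(np.linalg.norm(ab))
    if L <= 0:
        raise GeometryError("degenerate zero-deflection line")
    ab_unit = ab / L
    normal = np.array([-ab_unit[1], ab_unit[0]])  # y-up left normal of AB

    # Maximum deflection: perpendicular distance on the groove side
    # (below AB for a y-up frame with AB roughly horizontal).
    inner = mem[ia : ib + 1]
    signed = (inner - A) @ normal
    d = float(max(0.0, -signed.min()))

    # Endpoint tangents: membrane fitted on the groove side of each
    # contact point, substrate on the ridge-top side.
    window = max(cfg.tangent_window_frac * L, 1e-30)
    th_M_A = _endpoint_tangent_angle(
        _window_points(mem, ia, +1, window, cfg.tangent_min_points),
        A, ab_unit, normal, L, cfg.tangent_fit_degree,
    )
    th_M_B = _endpoint_tangent_angle(
        _window_points(mem, ib, -1, window, cfg.tangent_min_points),
        B, ab_unit, normal, L, cfg.tangent_fit_degree,
    )
    ja = int(np.clip(np.searchsorted(sub[:, 0], A[0], side="right") - 1,
                     0, sub.shape[0] - 1))
    jb = int(np.clip(np.searchsorted(sub[:, 0], B[0], side="left"),
                     0, sub.shape[0] - 1))
    th_S_A = _endpoint_tangent_angle(
        _window_points(sub, ja, -1, window, cfg.tangent_min_points),
        sub[ja], ab_unit, normal, L, cfg.tangent_fit_degree,
    )
    th_S_B = _endpoint_tangent_angle(
        _window_points(sub, jb, +1, window, cfg.tangent_min_points),
        sub[jb], ab_unit, normal, L, cfg.tangent_fit_degree,
    )

    return GrooveMeasurement(
        L=L,
        d=d,
        theta_M=0.5 * (th_M_A + th_M_B),
        theta_S=0.5 * (th_S_A + th_S_B),
        grating_class=profile.grating_class,
        groove_id=groove_id,
        endpoint_detail={
            "theta_M_A_deg": th_M_A,
            "theta_M_B_deg": th_M_B,
            "theta_S_A_deg": th_S_A,
            "theta_S_B_deg": th_S_B,
        },
    )


# ---------------------------------------------------------------------------
# cell-body morphometrics


def _polygon_moments(poly: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Signed area, centroid and central second area moments of a polygon.

    Uses the standard shoelace-based surface integrals; vertices need not
    be closed explicitly.
    """
    x, y = poly[:, 0], poly[:, 1]
    x1, y1 = np.roll(x, -1), np.roll(y, -1)
    cross = x * y1 - x1 * y
    area = 0.5 * float(cross.sum())
    if area == 0:
        raise ValueError("degenerate polygon: zero area")
    cx = float(((x + x1) * cross).sum() / (6.0 * area))
    cy = float(((y + y1) * cross).sum() / (6.0 * area))
    # raw second moments about the origin
    ixx = float(((y**2 + y * y1 + y1**2) * cross).sum() / 12.0)
    iyy = float(((x**2 + x * x1 + x1**2) * cross).sum() / 12.0)
    ixy = float(((x * y1 + 2 * x * y + 2 * x1 * y1 + x1 * y) * cross).sum() / 24.0)
    # shift to centroid
    a = abs(area)
    sgn = np.sign(area)
    mu = np.array(
        [
            [sgn * iyy - a * cx**2, sgn * ixy - a * cx * cy],
            [sgn * ixy - a * cx * cy, sgn * ixx - a * cy**2],
        ]
    )
    return a, np.array([cx, cy]), mu


def equimomental_ellipse(
    outline: np.ndarray | Sequence,
) -> tuple[float, float, float]:
    """(long_axis, short_axis, orientation_deg) of the equimomental ellipse.

    The ellipse with the same area and second central area moments as the
    outline polygon: a solid ellipse with semi-axes p >= q has
    moments (π/4)p³q and (π/4)pq³, giving semi-axes 2·sqrt(λ/A) from the
    eigenvalues λ of the central moment matrix.  Returned axes are full
    axis lengths (2× semi-axes); orientation is the long-axis angle in
    degrees, in (-90, 90].
    """
    poly = np.asarray(outline, dtype=float)
    if poly.ndim != 2 or poly.shape[1] != 2 or poly.shape[0] < 3:
        raise ValueError("outline must be an (n>=3, 2) polygon")
    area, _, mu = _polygon_moments(poly)
    evals, evecs = np.linalg.eigh(mu)  # ascending
    if np.any(evals <= 0):
        raise ValueError("degenerate polygon: non-positive second moment")
    semi = 2.0 * np.sqrt(evals / area)
    long_axis, short_axis = 2.0 * semi[1], 2.0 * semi[0]
    major_vec = evecs[:, 1]
    orientation = float(np.degrees(np.arctan2(major_vec[1], major_vec[0])))
    if orientation <= -90.0:
        orientation += 180.0
    elif orientation > 90.0:
        orientation -= 180.0
    return float(long_axis), float(short_axis), orientation


def elongation_parameter(long_axis: float, short_axis: float) -> float:
    """Elongation = long/short axis ratio minus one (0 for a circle)."""
    if short_axis <= 0:
        raise ValueError("short_axis must be > 0")
    if long_axis < short_axis:
        raise ValueError("long_axis must be >= short_axis")
    return long_axis / short_axis - 1.0


ELONGATION_THRESHOLD = 4.0
ALIGNMENT_ANGLE_DEG = 15.0


def is_aligned(
    cell_orientation: float, grating_axis: float, elongation: float
) -> bool:
    """Whether an elongated cell counts as aligned with the grating.

    True iff elongation >= 4 and the acute angle between the cell long
    axis and the grating axis (mod 180°, folded to [0°, 90°]) is strictly
    below 15°.
    """
    if not (np.isfinite(cell_orientation) and np.isfinite(grating_axis)):
        raise ValueError("orientations must be finite")
    diff = abs(cell_orientation - grating_axis) % 180.0
    if diff > 90.0:
        diff = 180.0 - diff
    return bool(elongation >= ELONGATION_THRESHOLD and diff < ALIGNMENT_ANGLE_DEG)


# ---------------------------------------------------------------------------
# bending-angle segmentation

BENDING_ANGLE_EDGES = (15.0, 30.0, 45.0)
BENDING_GROUP_LABELS = (
    "theta_M < 15",
    "15 <= theta_M < 30",
    "30 <= theta_M < 45",
    "theta_M >= 45",
)


def segment_by_bending_angle(
    records: Iterable[GrooveMeasurement],
) -> dict[str, dict]:
    """Partition groove records into the four membrane bending-angle groups.

    Half-open bins [0, 15), [15, 30), [30, 45), [45, inf) on theta_M
    (degrees).  Returns, per group, the member records and the mean/SD of
    theta_M, L and d/L (NaN for empty groups).
    """
    groups: dict[str, list[GrooveMeasurement]] = {
        label: [] for label in BENDING_GROUP_LABELS
    }
    for rec in records:
        i = int(np.searchsorted(BENDING_ANGLE_EDGES, rec.theta_M, side="right"))
        groups[BENDING_GROUP_LABELS[i]].append(rec)

    out: dict[str, dict] = {}
    for label, members in groups.items():
        if members:
            tm = np.array([r.theta_M for r in members])
            Ls = np.array([r.L for r in members])
            dl = np.array([r.dL for r in members])
            stats = {
                "n": len(members),
                "mean_theta_M_deg": float(tm.mean()),
                "sd_theta_M_deg": float(tm.std(ddof=1)) if len(members) > 1 else 0.0,
                "mean_L_m": float(Ls.mean()),
                "sd_L_m": float(Ls.std(ddof=1)) if len(members) > 1 else 0.0,
                "mean_dL": float(dl.mean()),
                "sd_dL": float(dl.std(ddof=1)) if len(members) > 1 else 0.0,
            }
        else:
            stats = {
                "n": 0,
                "mean_theta_M_deg": float("nan"),
                "sd_theta_M_deg": float("nan"),
                "mean_L_m": float("nan"),
                "sd_L_m": float("nan"),
                "mean_dL": float("nan"),
                "sd_dL": float("nan"),
            }
        out[label] = {"records": members, **stats}
    return out


# ---------------------------------------------------------------------------
# record I/O


def records_to_frame(records: Iterable[GrooveMeasurement]) -> pd.DataFrame:
    rows = []
    for rec in records:
        det = rec.endpoint_detail
        rows.append(
            {
                "groove_id": rec.groove_id,
                "grating_class": rec.grating_class,
                "L_m": rec.L,
                "d_m": rec.d,
                "dL": rec.dL,
                "theta_M_deg": rec.theta_M,
                "theta_S_deg": rec.theta_S,
                "theta_M_A_deg": det.get("theta_M_A_deg", rec.theta_M),
                "theta_M_B_deg": det.get("theta_M_B_deg", rec.theta_M),
                "theta_S_A_deg": det.get("theta_S_A_deg", rec.theta_S),
                "theta_S_B_deg": det.get("theta_S_B_deg", rec.theta_S),
            }
        )
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def write_records_csv(records: Iterable[GrooveMeasurement], path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def read_records_csv(path) -> list[GrooveMeasurement]:
    """Read groove records, skipping rows with non-finite values.

    Raises a schema error naming any missing required columns.
    """
    df = pd.read_csv(path)
    required = ["L_m", "d_m", "theta_M_deg", "theta_S_deg"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"records CSV is missing columns: {missing}")
    records = []
    for _, row in df.iterrows():
        vals = row[required].to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            continue
        records.append(
            GrooveMeasurement(
                L=float(row["L_m"]),
                d=float(row["d_m"]),
                theta_M=float(row["theta_M_deg"]),
                theta_S=float(row["theta_S_deg"]),
                grating_class=str(row.get("grating_class", "")),
                groove_id=str(row.get("groove_id", "")),
                endpoint_detail={
                    k: float(row[k])
                    for k in (
                        "theta_M_A_deg",
                        "theta_M_B_deg",
                        "theta_S_A_deg",
                        "theta_S_B_deg",
                    )
                    if k in df.columns and np.isfinite(row[k])
                },
            )
        )
    return records
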