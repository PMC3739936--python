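"""Ruled surface between two helix curves and its descriptors.

The surface is swept by a straight line (ruling) moving along the two
curves: both curves are discretized by the same number of points and the
k-th point of one curve is connected to the k-th point of the other.  For
the smooth descriptors the points sit at equal arc-length fractions along
each curve.  From the rulings we compute:

* the striction curve — feet of the common perpendicular of each pair of
  adjacent rulings, the natural spine of a skew ruled surface;
* the distribution parameter lambda (nm) — the winding rate of the
  tangent plane about a ruling, lambda = det(s', e, e') / |e'|^2, zero by
  convention on torsal stretches (adjacent rulings parallel or
  intersecting), where its computation is numerically unstable anyway;
* the conical curvature J (dimensionless) — the geodesic-curvature-type
  descriptor J = det(e, e', e'') / |e'|^3 of the spherical curve traced
  by the unit ruling directions (the director cone) on the unit sphere;
  positive J = left-hand bend of the spherical curve;
* the triangulated area between the curves, as absolute groove area and
  normalized per residue.

Discretely, derivatives are replaced by differences between adjacent
rulings; the difference-step scale cancels in each of the ratios above.
The discrete distribution parameter is evaluated from the directrix
points on curve A: det(delta a, e, delta e) is unchanged by replacing a
with any other directrix a + w e on the surface (the extra term has two
proportional columns), so the striction points themselves are not needed
in the ratio — which keeps lambda finite near torsal stretches.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .curve_model import FittedCurve
from .diffgeo import ParameterProfile
from .errors import DegenerateGeometryError
from .io_structures import HelixTrace

#: adjacent rulings with |e_k x e_{k+1}| below this are treated as torsal
EPS_TORSAL = 1e-6


@dataclass
class RuledSurface:
    """Discretized ruled surface between two curves.

    ``striction_points`` rows are NaN where the adjacent-ruling pair is
    torsal; ``torsal_flags`` has one entry per adjacent pair (length
    n_rulings - 1).
    """

    points_a: np.ndarray  # (n, 3) nm
    points_b: np.ndarray  # (n, 3) nm
    directions: np.ndarray  # (n, 3) unit vectors A -> B
    params: np.ndarray  # (n,) curve parameter of the rulings (A side)
    striction_points: np.ndarray | None = None  # (n-1, 3)
    torsal_flags: np.ndarray | None = None  # (n-1,) bool

    @property
    def n_rulings(self) -> int:
        return len(self.directions)

    @classmethod
    def from_rulings(cls, points_a, points_b, params=None) -> "RuledSurface":
        """Build directly from matched point pairs (fixture/oracle route)."""
        a = np.asarray(points_a, dtype=float)
        b = np.asarray(points_b, dtype=float)
        if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
            raise ValueError("point arrays must be matching (n, 3)")
        if len(a) < 4:
            raise ValueError("need at least 4 rulings")
        d = b - a
        norms = np.linalg.norm(d, axis=1)
        if np.any(norms < 1e-9):
            raise DegenerateGeometryError("coincident paired points")
        if params is None:
            params = np.arange(len(a), dtype=float)
        return cls(
            points_a=a,
            points_b=b,
            directions=d / norms[:, None],
            params=np.asarray(params, dtype=float),
        )


def _equal_arclength_params(curve: FittedCurve, n: int) -> np.ndarray:
    """Parameters placing n points at equal arc-length fractions."""
    lo, hi = curve.domain
    total = curve.arc_length(lo, hi)
    ts = np.empty(n)
    ts[0], ts[-1] = lo, hi
    for k in range(1, n - 1):
        target = total * k / (n - 1)
        ts[k] = brentq(
            lambda t: curve.arc_length(lo, t) - target, lo, hi, xtol=1e-10
        )
    return ts


def build_ruled_surface(
    curve_a: FittedCurve, curve_b: FittedCurve, n_rulings: int
) -> RuledSurface:
    """Connect equal-arc-length-fraction points of the two curves."""
    if n_rulings < 4:
        raise ValueError("n_rulings must be >= 4")
    ta = _equal_arclength_params(curve_a, n_rulings)
    tb = _equal_arclength_params(curve_b, n_rulings)
    a = curve_a.evaluate(ta)
    b = curve_b.evaluate(tb)
    rs = RuledSurface.from_rulings(a, b, params=ta)
    return rs


def striction_points(rs: RuledSurface) -> RuledSurface:
    """Feet of the common perpendicular of each adjacent ruling pair,
    taken on the first ruling of the pair.

    Pairs whose rulings are (nearly) parallel are flagged torsal and get
    no striction point: there the surface is torsal and the computation
    is numerically unstable.
    """
    n = rs.n_rulings
    s = np.full((n - 1, 3), np.nan)
    torsal = np.zeros(n - 1, dtype=bool)
    for k in range(n - 1):
        e1, e2 = rs.directions[k], rs.directions[k + 1]
        if np.linalg.norm(np.cross(e1, e2)) < EPS_TORSAL:
            torsal[k] = True
            continue
        w0 = rs.points_a[k] - rs.points_a[k + 1]
        b = float(e1 @ e2)
        d = float(e1 @ w0)
        e = float(e2 @ w0)
        u = (b * e - d) / (1.0 - b * b)
        s[k] = rs.points_a[k] + u * e1
    rs.striction_points = s
    rs.torsal_flags = torsal
    return rs


def distribution_parameter(rs: RuledSurface) -> ParameterProfile:
    """Discrete distribution parameter lambda_k (nm), one value per
    adjacent ruling pair; lambda = 0 at torsal pairs by convention."""
    if rs.torsal_flags is None:
        striction_points(rs)
    n = rs.n_rulings
    lam = np.zeros(n - 1)
    for k in range(n - 1):
        if rs.torsal_flags[k]:
            continue
        da = rs.points_a[k + 1] - rs.points_a[k]
        de = rs.directions[k + 1] - rs.directions[k]
        lam[k] = float(
            np.linalg.det(np.stack([da, rs.directions[k], de]))
            / (de @ de)
        )
    return ParameterProfile(
        descriptor="distribution_parameter",
        positions=np.arange(1, n),
        values=lam,
        window=1,
    )


def conical_curvature(rs: RuledSurface) -> ParameterProfile:
    """Discrete conical curvature J_k (dimensionless), one value per
    ruling.  Central differences of the unit directions in the interior,
    one-sided stencils at the two endpoints (lower confidence).  Where
    the direction is stationary (|delta e| below the torsal threshold)
    the position is reported missing (NaN)."""
    e = rs.directions
    n = rs.n_rulings
    J = np.full(n, np.nan)
    for k in range(n):
        if 0 < k < n - 1:
            d1 = (e[k + 1] - e[k - 1]) / 2.0
            d2 = e[k + 1] - 2.0 * e[k] + e[k - 1]
        elif k == 0:
            d1 = e[1] - e[0]
            d2 = e[2] - 2.0 * e[1] + e[0]
        else:
            d1 = e[n - 1] - e[n - 2]
            d2 = e[n - 1] - 2.0 * e[n - 2] + e[n - 3]
        norm = np.linalg.norm(d1)
        if norm < EPS_TORSAL:
            continue
        J[k] = float(np.linalg.det(np.stack([e[k], d1, d2])) / norm**3)
    return ParameterProfile(
        descriptor="conical_curvature",
        positions=np.arange(1, n + 1),
        values=J,
        window=1,
    )


def arctan_transform(profile: ParameterProfile) -> ParameterProfile:
    """Map conical-curvature values elementwise by arctan into
    (-pi/2, pi/2) for display on one scale (a logarithm would not do:
    J takes both signs)."""
    if profile.descriptor != "conical_curvature":
        raise ValueError("arctan transform applies to conical curvature only")
    return ParameterProfile(
        descriptor="conical_curvature_arctan",
        positions=profile.positions.copy(),
        values=np.arctan(profile.values),
        window=profile.window,
        aa_span=dict(profile.aa_span),
        helix_label=profile.helix_label,
        structure_id=profile.structure_id,
    )


def surface_profile_moving_average(
    profile: ParameterProfile, window: int = 4
) -> ParameterProfile:
    """Sliding unweighted mean over ``window`` consecutive striction
    positions (one average turn); input of length m gives m - window + 1
    output positions."""
    m = len(profile.values)
    if m < window:
        raise ValueError(f"need at least {window} positions, got {m}")
    kernel = np.ones(window) / window
    out = np.convolve(profile.values, kernel, mode="valid")
    return ParameterProfile(
        descriptor=profile.descriptor,
        positions=np.arange(1, m - window + 2),
        values=out,
        window=window,
        helix_label=profile.helix_label,
        structure_id=profile.structure_id,
    )


@dataclass(frozen=True)
class GrooveArea:
    """Triangulated area between the two groove helices (nm^2)."""

    a_total: float
    a_per_residue: float
    n_residues_used: int
    triangles: int


def _triangle_area(p, q, r) -> float:
    return 0.5 * float(np.linalg.norm(np.cross(q - p, r - p)))


def strip_area(points_a: np.ndarray, points_b: np.ndarray) -> tuple[float, int]:
    """Area of the triangulated strip between two matched point rows:
    triangles (a_i, b_i, a_{i+1}) and (b_i, a_{i+1}, b_{i+1})."""
    a = np.asarray(points_a, dtype=float)
    b = np.asarray(points_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("matched point rows must have equal shape")
    total = 0.0
    n_tri = 0
    for i in range(len(a) - 1):
        total += _triangle_area(a[i], b[i], a[i + 1])
        total += _triangle_area(b[i], a[i + 1], b[i + 1])
        n_tri += 2
    return total, n_tri


def groove_area(
    curve_a: FittedCurve,
    curve_b: FittedCurve,
    trace_a: HelixTrace,
    trace_b: HelixTrace,
    tail_exclusion: int = 3,
) -> GrooveArea:
    """Triangulated groove area, excluding ``tail_exclusion`` residues at
    the C-terminal end of each helix to avoid end artifacts.

    Curve points sit at the retained residue nodes when the two helices
    retain the same residue count (the natural correspondence for a
    per-residue-normalized area); otherwise both curves are resampled at
    max(n_a, n_b) evenly spaced parameter values over the retained span
    (the index parameter ticks once per residue, so this stays close to
    per-residue spacing).  The normalization divides by the total
    retained residue count.
    """
    if tail_exclusion < 0:
        raise ValueError("tail_exclusion must be >= 0")
    n_a = trace_a.n_res - tail_exclusion
    n_b = trace_b.n_res - tail_exclusion
    if n_a < 5 or n_b < 5:
        raise ValueError("fewer than 5 residues retained after tail exclusion")
    ta = curve_a.t_nodes[:n_a]
    tb = curve_b.t_nodes[:n_b]
    if n_a == n_b:
        pa = curve_a.evaluate(ta)
        pb = curve_b.evaluate(tb)
    else:
        m = max(n_a, n_b)
        fr = np.linspace(0.0, 1.0, m)
        pa = curve_a.evaluate(ta[0] + fr * (ta[-1] - ta[0]))
        pb = curve_b.evaluate(tb[0] + fr * (tb[-1] - tb[0]))
    total, n_tri = strip_area(pa, pb)
    return GrooveArea(
        a_total=total,
        a_per_residue=total / (n_a + n_b),
        n_residues_used=n_a + n_b,
        triangles=n_tri,
    )


def striction_xyz_tsv(rs: RuledSurface) -> str:
    """Striction-curve export for external visualization: one row per
    adjacent ruling pair with the striction point (nm) and torsal flag."""
    if rs.striction_points is None:
        striction_points(rs)
    buf = io.StringIO()
    buf.write("position\tx_nm\ty_nm\tz_nm\ttorsal\n")
    for k in range(rs.n_rulings - 1):
        p = rs.striction_points[k]
        flag = bool(rs.torsal_flags[k])
        if flag:
            buf.write(f"{k + 1}\t\t\t\t{flag}\n")
        else:
            buf.write(f"{k + 1}\t{p[0]!r}\t{p[1]!r}\t{p[2]!r}\t{flag}\n")
    return buf.getvalue()
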