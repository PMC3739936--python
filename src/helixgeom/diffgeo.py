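"""Frenet descriptors of fitted helix curves.

Local curvature kappa(t) = |c' x c''| / |c'|^3 (nm^-1) and local torsion
tau(t) = det(c', c'', c''') / |c' x c''|^2 (nm^-1) are evaluated from the
analytic derivatives of the polynomial curve.  For interpretation at the
residue scale both are reported as moving averages over a window of four
residues (about one helical turn): the value at position j is the
arc-length-weighted mean of the descriptor over the parameter interval
covered by residues j..j+3, i.e. (1/L_j) * int kappa |c'| dt with L_j the
window arc length, which normalizes the average to the length of the
curve.  Position j therefore spans amino acids j..j+window-1, and a helix
with n usable residues yields n - window + 1 positions.

The sign of tau encodes handedness of the twisting of the fitted axis
curve (positive = right-handed); it has no bearing on the handedness of
the backbone coil itself, which the polynomial model deliberately smooths
away.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import simpson

from .curve_model import FittedCurve
from .errors import DegenerateGeometryError
from .io_structures import HelixTrace

_EPS_SPEED = 1e-9  # nm per unit parameter; below this the tangent is degenerate
_EPS_KAPPA = 1e-12  # nm^-1; below this the binormal (and tau) is undefined

UNITS = {
    "curvature": "nm^-1",
    "torsion": "nm^-1",
    "distribution_parameter": "nm",
    "conical_curvature": "-",
    "conical_curvature_arctan": "rad",
}


@dataclass
class ParameterProfile:
    """Per-position values of one scalar descriptor along a helix or
    striction curve.  ``values`` may contain NaN for missing positions."""

    descriptor: str
    positions: np.ndarray  # 1-based window indices
    values: np.ndarray
    window: int = 4
    aa_span: dict[int, tuple[int, int]] = field(default_factory=dict)
    helix_label: str = ""
    structure_id: str = ""

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.positions) != len(self.values):
            raise ValueError("positions and values must have equal length")

    @property
    def units(self) -> str:
        return UNITS.get(self.descriptor, "")

    def to_tsv(self) -> str:
        """TSV export with one row per position."""
        buf = io.StringIO()
        buf.write("position\taa_start\taa_end\tvalue\tunits\tdescriptor\thelix_label\tstructure_id\n")
        for p, v in zip(self.positions, self.values):
            span = self.aa_span.get(int(p), ("", ""))
            buf.write(
                f"{p}\t{span[0]}\t{span[1]}\t{v!r}\t{self.units}\t"
                f"{self.descriptor}\t{self.helix_label}\t{self.structure_id}\n"
            )
        return buf.getvalue()


def local_curvature(curve: FittedCurve, t) -> float | np.ndarray:
    """Local curvature kappa(t) >= 0 in nm^-1; 1/kappa is the radius of
    the circle of curvature."""
    tt = np.atleast_1d(np.asarray(t, dtype=float))
    d1 = curve.evaluate(tt, 1)
    d2 = curve.evaluate(tt, 2)
    speed = np.linalg.norm(d1, axis=-1)
    if np.any(speed < _EPS_SPEED):
        raise DegenerateGeometryError("vanishing tangent: curvature undefined")
    cross = np.cross(d1, d2)
    kappa = np.linalg.norm(cross, axis=-1) / speed**3
    return float(kappa[0]) if np.isscalar(t) or np.ndim(t) == 0 else kappa


def local_torsion(curve: FittedCurve, t) -> float | np.ndarray:
    """Local torsion tau(t) in nm^-1; positive = right-handed twisting
    (anti-clockwise rotation of the binormal about the tangent)."""
    tt = np.atleast_1d(np.asarray(t, dtype=float))
    d1 = curve.evaluate(tt, 1)
    d2 = curve.evaluate(tt, 2)
    d3 = curve.evaluate(tt, 3)
    cross = np.cross(d1, d2)
    denom = np.sum(cross**2, axis=-1)
    speed = np.linalg.norm(d1, axis=-1)
    if np.any(np.sqrt(denom) < _EPS_KAPPA * speed**3):
        raise DegenerateGeometryError(
            "vanishing curvature: torsion undefined on straight segments"
        )
    tau = np.einsum("...i,...i->...", cross, d3) / denom
    return float(tau[0]) if np.isscalar(t) or np.ndim(t) == 0 else tau


def _window_average(
    curve: FittedCurve, t0: float, t1: float, descriptor: str, n_grid: int = 129
) -> float:
    """Arc-length-weighted mean of a descriptor over [t0, t1].

    Points where the descriptor is undefined (degenerate tangent, or
    kappa ~ 0 for torsion) are excluded; if more than half of the window
    arc is undefined the position is reported missing (NaN).
    """
    tg = np.linspace(t0, t1, n_grid)
    d1 = curve.evaluate(tg, 1)
    d2 = curve.evaluate(tg, 2)
    speed = np.linalg.norm(d1, axis=-1)
    cross = np.cross(d1, d2)
    cross_norm = np.linalg.norm(cross, axis=-1)

    ok = speed > _EPS_SPEED
    if descriptor == "curvature":
        f = np.zeros_like(tg)
        f[ok] = cross_norm[ok] / speed[ok] ** 3
    elif descriptor == "torsion":
        ok &= cross_norm > _EPS_KAPPA * np.maximum(speed, _EPS_SPEED) ** 3
        d3 = curve.evaluate(tg, 3)
        f = np.zeros_like(tg)
        f[ok] = np.einsum("ij,ij->i", cross[ok], d3[ok]) / cross_norm[ok] ** 2
    else:
        raise ValueError(f"unsupported descriptor {descriptor!r}")

    w = np.where(ok, speed, 0.0)
    total_arc = simpson(speed, x=tg)
    defined_arc = simpson(w, x=tg)
    if defined_arc < 0.5 * total_arc or defined_arc <= 0:
        return float("nan")
    return float(simpson(f * w, x=tg) / defined_arc)


def profile_moving_average(
    curve: FittedCurve,
    trace: HelixTrace,
    descriptor: str,
    window: int = 4,
) -> ParameterProfile:
    """Turn-averaged curvature or torsion profile of one helix.

    Position j (1-based) covers residues j..j+window-1 of the trace and
    holds the arc-length-weighted mean of the local descriptor over the
    parameter span of those residues.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    n = trace.n_res
    if n < window + 1:
        raise ValueError(f"need at least {window + 1} residues, got {n}")
    t = curve.t_nodes
    n_pos = n - window + 1
    values = np.empty(n_pos)
    aa_span: dict[int, tuple[int, int]] = {}
    for j in range(1, n_pos + 1):
        t0, t1 = float(t[j - 1]), float(t[j + window - 2])
        values[j - 1] = _window_average(curve, t0, t1, descriptor)
        aa_span[j] = (trace.residue_ids[j - 1], trace.residue_ids[j + window - 2])
    return ParameterProfile(
        descriptor=descriptor,
        positions=np.arange(1, n_pos + 1),
        values=values,
        window=window,
        aa_span=aa_span,
        helix_label=trace.helix_label,
    )


def drop_end_windows(
    profile: ParameterProfile, tail: int = 4, head: int = 0
) -> ParameterProfile:
    """Reporting helper: drop positions whose window overlaps the first
    ``head`` / last ``tail`` residues of the helix, for excluding the
    frayed terminal turn from analysis.  Positions keep their original
    numbering."""
    n_pos = len(profile.positions)
    n_res = n_pos + profile.window - 1
    keep = [
        i
        for i, j in enumerate(profile.positions)
        if j > head and j + profile.window - 1 <= n_res - tail
    ]
    return ParameterProfile(
        descriptor=profile.descriptor,
        positions=profile.positions[keep],
        values=profile.values[keep],
        window=profile.window,
        aa_span={int(profile.positions[i]): profile.aa_span.get(int(profile.positions[i]), ("", "")) for i in keep},
        helix_label=profile.helix_label,
        structure_id=profile.structure_id,
    )
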