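"""Polynomial space-curve models of helix traces.

Each helix trace is represented by one smooth curve c(t) with a polynomial
per spatial coordinate over a shared parameter t.  The three coordinate
polynomials share one degree, selected by the corrected Akaike information
criterion (AICc) over candidate degrees; the least-squares fit may be
weighted (e.g. by inverse B-factors).  The low-degree polynomial is itself
the smoother: it abstracts away the periodic helical turns and follows the
helix as a whole object, which is exactly what the downstream curvature,
torsion and ruled-surface descriptors consume.

Internally the polynomials are stored in a Chebyshev basis mapped to the
fit domain for numerical conditioning; this is an implementation detail —
the model class is an ordinary degree-d polynomial curve.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numpy.polynomial import Chebyshev
from scipy.integrate import quad

from .errors import DomainError, HelixGeomError
from .io_structures import HelixTrace

#: ``rss`` below this (scaled) floor counts as a numerically perfect fit;
#: the smallest such degree wins outright (the AICc log term is pure
#: floating-point noise there).
_PERFECT_RSS_FACTOR = 1e-22

#: default cap on the candidate degree, guarding against Runge oscillation
#: on long helices
DEFAULT_MAX_DEGREE = 12


def aicc(rss: float, n: int, k: int) -> float:
    """Corrected Akaike criterion  n*ln(rss/n) + 2k + 2k(k+1)/(n-k-1).

    ``n`` is the number of scalar observations entering ``rss`` and ``k``
    the number of fitted coefficients.  Returns ``+inf`` when the degree
    must be excluded (n <= k+1) and ``-inf`` for a perfect fit (rss = 0).
    Lower is better.
    """
    if rss < 0:
        raise ValueError("rss must be >= 0")
    if n <= k + 1:
        return np.inf  # correction term undefined: degree excluded, not an error
    if rss == 0.0:
        return -np.inf
    return float(n * np.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1))


@dataclass
class FittedCurve:
    """Polynomial curve c(t) = (x(t), y(t), z(t)) with shared degree."""

    polys: list[Chebyshev]  # three series over a common domain
    degree: int
    t_nodes: np.ndarray
    domain: tuple[float, float]
    rss: float  # (weighted) residual sum of squares, nm^2
    weights_used: np.ndarray | None = None
    _derivs: dict[int, list[Chebyshev]] = field(default_factory=dict, repr=False)

    def _series(self, order: int) -> list[Chebyshev]:
        if order == 0:
            return self.polys
        if order not in self._derivs:
            self._derivs[order] = [p.deriv(order) for p in self.polys]
        return self._derivs[order]

    def evaluate(self, t, order: int = 0) -> np.ndarray:
        """Exact analytic value or derivative (order 0..3) of the curve.

        Returns shape (3,) for scalar ``t``, (len(t), 3) for a grid.
        Extrapolation outside the fit domain is refused.
        """
        if not 0 <= order <= 3:
            raise ValueError("derivative order must be in 0..3")
        tt = np.asarray(t, dtype=float)
        lo, hi = self.domain
        tol = 1e-9 * max(1.0, abs(lo), abs(hi))
        if np.any(tt < lo - tol) or np.any(tt > hi + tol):
            raise DomainError(f"t outside fit domain [{lo}, {hi}]")
        series = self._series(order)
        out = np.stack([p(tt) for p in series], axis=-1)
        return out

    def arc_length(self, t0: float, t1: float) -> float:
        """Arc length of the curve between t0 and t1 (adaptive quadrature)."""
        if t1 < t0:
            raise ValueError("t0 must be <= t1")
        lo, hi = self.domain
        tol = 1e-9 * max(1.0, abs(lo), abs(hi))
        if t0 < lo - tol or t1 > hi + tol:
            raise DomainError(f"[{t0}, {t1}] outside fit domain [{lo}, {hi}]")
        speed = lambda t: float(np.linalg.norm(self.evaluate(t, order=1)))
        val, _ = quad(speed, t0, t1, epsrel=1e-9, limit=200)
        return float(val)

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "degree": self.degree,
            "domain": list(self.domain),
            "t_nodes": self.t_nodes.tolist(),
            "coef": [p.coef.tolist() for p in self.polys],
            "rss": self.rss,
            "weights": None
            if self.weights_used is None
            else self.weights_used.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FittedCurve":
        domain = tuple(d["domain"])
        polys = [Chebyshev(np.array(c), domain=domain) for c in d["coef"]]
        w = d.get("weights")
        return cls(
            polys=polys,
            degree=int(d["degree"]),
            t_nodes=np.array(d["t_nodes"], dtype=float),
            domain=domain,
            rss=float(d["rss"]),
            weights_used=None if w is None else np.array(w, dtype=float),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def from_json(cls, path: str | Path) -> "FittedCurve":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _fit_fixed_degree(
    t: np.ndarray, pts: np.ndarray, degree: int, w: np.ndarray | None
) -> tuple[list[Chebyshev], float]:
    domain = [float(t.min()), float(t.max())]
    # numpy's ``w`` multiplies residuals, so pass sqrt of the statistical weight
    wfit = None if w is None else np.sqrt(w)
    polys = []
    rss = 0.0
    for dim in range(3):
        p = Chebyshev.fit(t, pts[:, dim], deg=degree, domain=domain, w=wfit)
        r = pts[:, dim] - p(t)
        rss += float(np.sum((w if w is not None else 1.0) * r**2))
        polys.append(p)
    return polys, rss


def parameter_nodes(trace: HelixTrace, parameterization: str = "index") -> np.ndarray:
    """Curve parameter assigned to each residue of a trace.

    ``index``: residue ordinal offset from the first residue; gaps in the
    residue numbering stay as skipped integers, so the parameterization is
    gap-aware.  ``chord``: cumulative chord length of the C-alpha polyline.
    """
    if parameterization == "index":
        return np.array(
            [r - trace.residue_ids[0] for r in trace.residue_ids], dtype=float
        )
    if parameterization == "chord":
        d = np.linalg.norm(np.diff(trace.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(d)])
    raise ValueError(f"unknown parameterization {parameterization!r}")


def fit_polynomial_curve(
    trace: HelixTrace,
    weights: np.ndarray | None = None,
    max_degree: int | None = None,
    parameterization: str = "index",
) -> FittedCurve:
    """Fit a helix trace by a polynomial curve with AICc degree selection.

    Candidate degrees run 1..min(max_degree, n_res - 2).  The selection
    score counts all scalar observations (n = 3 * n_res) against the joint
    coefficient count k = 3 * (degree + 1); degrees whose correction term
    is undefined (n <= k + 1) are excluded from the sweep.  With
    ``weights`` (e.g. inverse B-factors) the per-coordinate fits and the
    rss entering the score are weighted.  Deterministic.
    """
    if max_degree is None:
        max_degree = min(DEFAULT_MAX_DEGREE, trace.n_res - 2)
    if max_degree < 1:
        raise ValueError("max_degree must be >= 1")
    w = None
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        if w.shape != (trace.n_res,):
            raise ValueError("weights must match the number of residues")
        if np.any(w <= 0):
            raise ValueError("weights must be > 0")

    t = parameter_nodes(trace, parameterization)
    if len(np.unique(t)) != len(t):
        raise HelixGeomError("duplicate parameter nodes (rank-deficient design)")
    pts = trace.points

    n_obs = 3 * trace.n_res
    scale = max(1.0, float(np.mean(np.sum(pts**2, axis=1))))
    perfect = _PERFECT_RSS_FACTOR * n_obs * scale

    best: tuple[float, int, list[Chebyshev], float] | None = None
    hi = min(max_degree, trace.n_res - 2)
    for d in range(1, hi + 1):
        k = 3 * (d + 1)
        if n_obs <= k + 1:
            continue
        polys, rss = _fit_fixed_degree(t, pts, d, w)
        score = aicc(0.0 if rss <= perfect else rss, n_obs, k)
        # strict < keeps the lowest degree among numerically perfect fits
        if best is None or score < best[0]:
            best = (score, d, polys, rss)
    if best is None:
        raise HelixGeomError("no admissible degree (trace too short)")
    _, d, polys, rss = best
    return FittedCurve(
        polys=polys,
        degree=d,
        t_nodes=t,
        domain=(float(t.min()), float(t.max())),
        rss=rss,
        weights_used=w,
    )


def eval_curve(curve: FittedCurve, t, order: int = 0) -> np.ndarray:
    """Module-level alias for :meth:`FittedCurve.evaluate`."""
    return curve.evaluate(t, order=order)


def arc_length(curve: FittedCurve, t0: float, t1: float) -> float:
    """Module-level alias for :meth:`FittedCurve.arc_length`."""
    return curve.arc_length(t0, t1)
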