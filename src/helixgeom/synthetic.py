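"""Analytic fixtures with known closed-form geometry.

Every generator here produces inputs whose curvature, torsion,
distribution parameter and conical curvature are known in closed form
(circular helix, helicoid, cylinder, cone) or computable by an
independent dense finite-difference oracle (offset helix pair).  The
expected values are never produced by the analysis code itself, so the
fixtures double as oracles for the whole pipeline without requiring any
structure download.

A circular helix (r cos t, r sin t, c t) has constant curvature
kappa = r / (r^2 + c^2) and torsion tau = +-c / (r^2 + c^2), the sign
given by handedness.  The realistic preset (r = 0.23 nm, rise 0.15 nm
per residue, 100 degrees per residue) approximates an alpha-helix
C-alpha trace, so fitted-degree behaviour resembles real inputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from .io_structures import ANGSTROM_PER_NM, HelixTrace
from .ruled_surface import RuledSurface

DEFAULT_NOISE_SD = 0.005  # nm, iid isotropic Gaussian on coordinates


@dataclass(frozen=True)
class AnalyticHelixSpec:
    radius: float  # nm
    pitch_rate: float  # nm per radian (z advance / angle)
    turns: float
    points_per_turn: float = 10.0
    noise_sd: float = 0.0
    seed: int = 0
    handedness: str = "right"

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be > 0")
        if self.points_per_turn < 3:
            raise ValueError("points_per_turn must be >= 3")
        if self.handedness not in ("right", "left"):
            raise ValueError("handedness must be 'right' or 'left'")


def realistic_helix_spec(
    turns: float = 9.0, noise_sd: float = 0.0, seed: int = 0
) -> AnalyticHelixSpec:
    """Alpha-helix-like preset: 0.23 nm radius, 0.15 nm rise and 100
    degrees of phase per residue (3.6 residues per turn)."""
    per_residue_angle = np.deg2rad(100.0)
    return AnalyticHelixSpec(
        radius=0.23,
        pitch_rate=0.15 / per_residue_angle,
        turns=turns,
        points_per_turn=3.6,
        noise_sd=noise_sd,
        seed=seed,
    )


def make_circular_helix(
    spec: AnalyticHelixSpec,
) -> tuple[HelixTrace, float, float]:
    """Sampled circular helix plus its closed-form (kappa, tau).

    Deterministic given the seed.  Consecutive-distance warnings from
    the trace check are suppressed: the fixture geometry is free to
    leave the protein-like range.
    """
    r, c = spec.radius, spec.pitch_rate
    n = int(round(spec.turns * spec.points_per_turn))
    t = np.linspace(0.0, 2.0 * np.pi * spec.turns, n)
    sign = 1.0 if spec.handedness == "right" else -1.0
    pts = np.column_stack([r * np.cos(t), r * np.sin(t), sign * c * t])
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        pts = pts + rng.normal(0.0, spec.noise_sd, size=pts.shape)
    kappa = r / (r**2 + c**2)
    tau = sign * c / (r**2 + c**2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        trace = HelixTrace(
            helix_label="analytic-helix",
            residue_ids=list(range(1, n + 1)),
            points=pts,
            b_factors=np.full(n, 20.0),
        )
    return trace, kappa, tau


@dataclass(frozen=True)
class AnalyticRuledSpec:
    family: str  # helicoid | cylinder | cone | offset-helix-pair
    n_rulings: int = 100
    parameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_rulings < 4:
            raise ValueError("n_rulings must be >= 4")


@dataclass
class RuledFixture:
    """A ruling set plus its independently known descriptors.

    ``expected_lambda`` is aligned with adjacent-ruling pairs (length
    n_rulings - 1), ``expected_J`` with rulings (length n_rulings); both
    hold the closed-form (or dense finite-difference) values of the
    continuous surface at those parameters.
    """

    surface: RuledSurface
    expected_lambda: np.ndarray
    expected_J: np.ndarray
    torsal_expected: bool = False


def _fd_ruled_oracle(a_of_u, b_of_u, u: np.ndarray, h: float = 1e-6):
    """Dense central finite-difference oracle for lambda(u) and J(u) of
    the continuous ruled surface x(u, v) = a(u) + v e(u).  Independent
    of the discrete estimators under test."""

    def e_of_u(uu):
        d = b_of_u(uu) - a_of_u(uu)
        return d / np.linalg.norm(d, axis=-1, keepdims=True)

    ap = (a_of_u(u + h) - a_of_u(u - h)) / (2 * h)
    ep = (e_of_u(u + h) - e_of_u(u - h)) / (2 * h)
    epp = (e_of_u(u + h) - 2 * e_of_u(u) + e_of_u(u - h)) / h**2
    e = e_of_u(u)
    # det(a', e, e') = a' . (e x e')
    lam = np.einsum("ij,ij->i", ap, np.cross(e, ep)) / np.einsum(
        "ij,ij->i", ep, ep
    )
    J = np.einsum("ij,ij->i", e, np.cross(ep, epp)) / np.linalg.norm(ep, axis=-1) ** 3
    return lam, J


def make_ruled_fixture(spec: AnalyticRuledSpec) -> RuledFixture:
    """Two matched point rows whose ruled surface has known descriptors.

    Families: ``helicoid`` (axis + unit-circle offsets; lambda = b,
    J = 0), ``cylinder`` (parallel rulings; torsal everywhere,
    lambda = 0), ``cone`` (rulings through one apex, half-angle alpha;
    lambda = 0, |J| = cot(alpha)), ``offset-helix-pair`` (two coaxial
    circular helices; expectations from the finite-difference oracle).
    """
    n = spec.n_rulings
    p = spec.parameters
    u = np.linspace(0.0, 2.0 * np.pi, n)

    if spec.family == "helicoid":
        b = float(p.get("b", 0.5))
        pa = np.column_stack([np.zeros(n), np.zeros(n), b * u])
        pb = pa + np.column_stack([np.cos(u), np.sin(u), np.zeros(n)])
        rs = RuledSurface.from_rulings(pa, pb, params=u)
        return RuledFixture(
            surface=rs,
            expected_lambda=np.full(n - 1, b),
            expected_J=np.zeros(n),
        )

    if spec.family == "cylinder":
        r = float(p.get("radius", 1.0))
        length = float(p.get("length", 1.0))
        pa = np.column_stack([r * np.cos(u), r * np.sin(u), np.zeros(n)])
        pb = pa + np.array([0.0, 0.0, length])
        rs = RuledSurface.from_rulings(pa, pb, params=u)
        return RuledFixture(
            surface=rs,
            expected_lambda=np.zeros(n - 1),
            expected_J=np.full(n, np.nan),
            torsal_expected=True,
        )

    if spec.family == "cone":
        alpha = float(p.get("half_angle", np.pi / 4))
        e = np.column_stack(
            [
                np.sin(alpha) * np.cos(u),
                np.sin(alpha) * np.sin(u),
                np.full(n, np.cos(alpha)),
            ]
        )
        pa = np.zeros((n, 3))  # all rulings share the apex
        rs = RuledSurface.from_rulings(pa, pa + e, params=u)
        return RuledFixture(
            surface=rs,
            expected_lambda=np.zeros(n - 1),
            expected_J=np.full(n, 1.0 / np.tan(alpha)),
        )

    if spec.family == "offset-helix-pair":
        r1 = float(p.get("r1", 1.0))
        r2 = float(p.get("r2", 1.6))
        c = float(p.get("c", 0.3))
        phase = float(p.get("phase", 0.4))
        dz = float(p.get("dz", 0.2))

        def a_of_u(uu):
            uu = np.atleast_1d(uu)
            return np.column_stack([r1 * np.cos(uu), r1 * np.sin(uu), c * uu])

        def b_of_u(uu):
            uu = np.atleast_1d(uu)
            return np.column_stack(
                [r2 * np.cos(uu + phase), r2 * np.sin(uu + phase), c * uu + dz]
            )

        lam, J = _fd_ruled_oracle(a_of_u, b_of_u, u)
        rs = RuledSurface.from_rulings(a_of_u(u), b_of_u(u), params=u)
        # lambda is a pair quantity: evaluate the oracle at pair midpoints
        mid = 0.5 * (u[:-1] + u[1:])
        lam_mid, _ = _fd_ruled_oracle(a_of_u, b_of_u, mid)
        return RuledFixture(surface=rs, expected_lambda=lam_mid, expected_J=J)

    raise ValueError(f"unsupported ruled-surface family {spec.family!r}")


def write_toy_pdb(traces: list[HelixTrace], path: str | Path) -> None:
    """Write C-alpha-only traces as a PDB file, one chain per trace
    (A, B, C, ...), coordinates nm -> Angstrom, B-factors preserved."""
    if not traces:
        raise ValueError("no traces to write")
    st = gemmi.Structure()
    st.name = "toy"
    model = gemmi.Model(1)
    for idx, trace in enumerate(traces):
        chain = gemmi.Chain(chr(ord("A") + idx))
        for rid, pt, b in zip(trace.residue_ids, trace.points, trace.b_factors):
            res = gemmi.Residue()
            res.name = "ALA"
            res.seqid = gemmi.SeqId(int(rid), " ")
            res.het_flag = "A"
            at = gemmi.Atom()
            at.name = "CA"
            at.element = gemmi.Element("C")
            at.pos = gemmi.Position(*(np.asarray(pt) * ANGSTROM_PER_NM))
            at.b_iso = float(b)
            at.occ = 1.0
            res.add_atom(at)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.write_pdb(str(path))
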