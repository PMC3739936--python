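"""End-to-end per-structure analysis wiring the modules together.

For one structure: extract the two groove-helix traces, optionally
superpose onto a reference (all descriptor signs — torsion, distribution
parameter, conical curvature — depend on the shared frame, so group
comparisons require one fixed reference for every structure), fit the
curves, and compute all six descriptors: per-helix averaged curvature and
torsion, the ruled surface's averaged distribution parameter and conical
curvature, and the two groove areas.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import diffgeo, ruled_surface as rsmod
from .config import RunConfig
from .curve_model import FittedCurve, fit_polynomial_curve
from .io_structures import (
    HelixTrace,
    StructureModel,
    extract_helix_trace,
    kabsch_superpose,
    read_structure,
)


@dataclass
class StructureAnalysis:
    structure_id: str
    traces: list[HelixTrace]
    curves: list[FittedCurve]
    profiles: dict[str, diffgeo.ParameterProfile]  # keyed like "G-ALPHA1/curvature"
    surface: rsmod.RuledSurface
    lambda_avg: diffgeo.ParameterProfile
    conical_avg: diffgeo.ParameterProfile
    conical_avg_arctan: diffgeo.ParameterProfile
    area: rsmod.GrooveArea


def _superpose_traces(
    traces: list[HelixTrace], ref_traces: list[HelixTrace]
) -> list[HelixTrace]:
    """Superpose using the C-alpha atoms of both configured helices,
    pairing residues present in both mobile and reference traces."""
    mob_pts, ref_pts = [], []
    for tr, rtr in zip(traces, ref_traces):
        ref_map = {rid: p for rid, p in zip(rtr.residue_ids, rtr.points)}
        for rid, p in zip(tr.residue_ids, tr.points):
            if rid in ref_map:
                mob_pts.append(p)
                ref_pts.append(ref_map[rid])
    tf, _ = kabsch_superpose(np.array(mob_pts), np.array(ref_pts))
    out = []
    for tr in traces:
        out.append(
            HelixTrace(
                helix_label=tr.helix_label,
                residue_ids=tr.residue_ids,
                points=tf.apply(tr.points),
                b_factors=tr.b_factors,
                gaps=tr.gaps,
            )
        )
    return out


def resolve_n_rulings(config: RunConfig, traces: list[HelixTrace]) -> int:
    if config.n_rulings != "auto":
        return int(config.n_rulings)
    retained = [t.n_res for t in traces]
    return int(round(float(np.mean(retained))))


def analyze_structure(
    path: str,
    config: RunConfig,
    reference: StructureModel | None = None,
) -> StructureAnalysis:
    model = read_structure(path)
    traces = [
        extract_helix_trace(model, h.chain, h.residue_range, h.label)
        for h in config.helices
    ]
    if reference is not None:
        ref_traces = [
            extract_helix_trace(reference, h.chain, h.residue_range, h.label)
            for h in config.helices
        ]
        traces = _superpose_traces(traces, ref_traces)

    curves = []
    for tr in traces:
        weights = 1.0 / tr.b_factors if config.weighting == "inverse_b" else None
        curves.append(fit_polynomial_curve(tr, weights=weights))

    profiles: dict[str, diffgeo.ParameterProfile] = {}
    for tr, cv in zip(traces, curves):
        for desc in ("curvature", "torsion"):
            prof = diffgeo.profile_moving_average(cv, tr, desc, window=config.window)
            if config.trim_tail_windows:
                prof = diffgeo.drop_end_windows(prof, tail=config.trim_tail_windows)
            prof.structure_id = model.id
            profiles[f"{tr.helix_label}/{desc}"] = prof

    n_rulings = resolve_n_rulings(config, traces)
    surface = rsmod.build_ruled_surface(curves[0], curves[1], n_rulings)
    rsmod.striction_points(surface)
    lam = rsmod.distribution_parameter(surface)
    con = rsmod.conical_curvature(surface)
    lam_avg = rsmod.surface_profile_moving_average(lam, window=config.window)
    con_avg = rsmod.surface_profile_moving_average(con, window=config.window)
    for prof in (lam_avg, con_avg):
        prof.structure_id = model.id
    con_avg_atan = diffgeo.ParameterProfile(
        descriptor="conical_curvature_arctan",
        positions=con_avg.positions.copy(),
        values=np.arctan(con_avg.values),
        window=con_avg.window,
        structure_id=model.id,
    )
    area = rsmod.groove_area(
        curves[0], curves[1], traces[0], traces[1], tail_exclusion=config.tail_exclusion
    )
    return StructureAnalysis(
        structure_id=model.id,
        traces=traces,
        curves=curves,
        profiles=profiles,
        surface=surface,
        lambda_avg=lam_avg,
        conical_avg=con_avg,
        conical_avg_arctan=con_avg_atan,
        area=area,
    )
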