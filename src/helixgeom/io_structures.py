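"""Reading protein structures and extracting helix C-alpha traces.

Coordinates are stored in nanometres throughout the package (PDB files are
in Angstrom; the conversion happens once, at read time).  Only the first
MODEL of a file is used, and alternate conformations are resolved to a
single atom per (residue, atom name) by keeping the location with the
highest occupancy (alphabetical altloc id breaks ties).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from .errors import DegenerateGeometryError, FormatError, InsufficientTraceError

ANGSTROM_PER_NM = 10.0


@dataclass(frozen=True)
class Atom:
    chain_id: str
    res_seq: int
    insertion_code: str
    atom_name: str
    alt_loc: str
    coords: np.ndarray  # (3,) in nm
    b_factor: float
    occupancy: float


@dataclass
class StructureModel:
    """All atoms of the first MODEL of a structure file, in file order."""

    id: str
    atoms: list[Atom]

    def __post_init__(self) -> None:
        for a in self.atoms:
            if not np.all(np.isfinite(a.coords)):
                raise FormatError(f"non-finite coordinates in {self.id}")


@dataclass
class HelixTrace:
    """Ordered C-alpha coordinates (nm) of one helix, with residue ids
    and B-factors.  ``gaps`` records residue numbers that were requested
    but had no usable C-alpha."""

    helix_label: str
    residue_ids: list[int]
    points: np.ndarray  # (n, 3) nm
    b_factors: np.ndarray  # (n,)
    gaps: list[int] = field(default_factory=list)

    @property
    def n_res(self) -> int:
        return len(self.residue_ids)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.b_factors = np.asarray(self.b_factors, dtype=float)
        if not (len(self.points) == len(self.residue_ids) == len(self.b_factors)):
            raise ValueError("points, residue_ids and b_factors must have equal length")
        if self.n_res < 5:
            raise InsufficientTraceError(
                f"helix {self.helix_label!r}: {self.n_res} residues (< 5)"
            )
        if any(b >= a for a, b in zip(self.residue_ids[1:], self.residue_ids)):
            raise ValueError("residue_ids must be strictly increasing")
        d = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if np.any((d < 0.2) | (d > 0.6)):
            warnings.warn(
                f"helix {self.helix_label!r}: consecutive C-alpha distances outside "
                f"(0.2, 0.6) nm (min {d.min():.3f}, max {d.max():.3f})",
                stacklevel=2,
            )


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x -> R x + t (nm)."""

    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        if np.abs(R.T @ R - np.eye(3)).max() > 1e-9:
            raise ValueError("rotation matrix is not orthonormal")
        if abs(np.linalg.det(R) - 1.0) > 1e-9:
            raise ValueError("rotation matrix is not proper (det != +1)")

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ np.asarray(self.rotation).T + self.translation


def read_structure(path: str | Path) -> StructureModel:
    """Read a PDB (or mmCIF) file into a :class:`StructureModel`.

    Keeps every ATOM/HETATM record of the first MODEL, converts
    Angstrom -> nm, and resolves altloc duplicates by highest occupancy.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"{path}: {exc}") from exc
    if len(st) == 0:
        raise FormatError(f"{path}: no MODEL found")
    model = st[0]

    # group altloc variants of the same atom; keep highest occupancy,
    # alphabetical altloc id on ties
    groups: dict[tuple, list[Atom]] = {}
    order: list[tuple] = []
    for chain in model:
        for res in chain:
            for at in res:
                atom = Atom(
                    chain_id=chain.name,
                    res_seq=res.seqid.num,
                    insertion_code=(res.seqid.icode or "").strip(),
                    atom_name=at.name,
                    alt_loc=(at.altloc or "").strip(),
                    coords=np.array(
                        [at.pos.x, at.pos.y, at.pos.z], dtype=float
                    )
                    / ANGSTROM_PER_NM,
                    b_factor=float(at.b_iso),
                    occupancy=float(at.occ),
                )
                key = (chain.name, res.seqid.num, atom.insertion_code, at.name)
                if key not in groups:
                    groups[key] = []
                    order.append(key)
                groups[key].append(atom)

    atoms: list[Atom] = []
    for key in order:
        variants = groups[key]
        variants.sort(key=lambda a: (-a.occupancy, a.alt_loc))
        atoms.append(variants[0])
    if not atoms:
        raise FormatError(f"{path}: no ATOM records")
    return StructureModel(id=path.stem, atoms=atoms)


def extract_helix_trace(
    model: StructureModel,
    chain_id: str,
    residue_range: tuple[int, int],
    label: str,
) -> HelixTrace:
    """Ordered C-alpha trace of residues ``residue_range`` (inclusive) in
    ``chain_id``.  Residues missing a C-alpha are skipped with a warning
    and listed in ``trace.gaps``."""
    lo, hi = residue_range
    if hi < lo:
        raise ValueError(f"empty residue range {residue_range}")
    by_res: dict[int, Atom] = {}
    for a in model.atoms:
        if a.chain_id == chain_id and a.atom_name == "CA" and lo <= a.res_seq <= hi:
            by_res.setdefault(a.res_seq, a)
    ids = sorted(by_res)
    gaps = [r for r in range(lo, hi + 1) if r not in by_res]
    if gaps:
        warnings.warn(
            f"{model.id} chain {chain_id}: no C-alpha for residues {gaps} "
            f"in range {lo}-{hi}; skipped",
            stacklevel=2,
        )
    if len(ids) < 5:
        raise InsufficientTraceError(
            f"{model.id} chain {chain_id} {lo}-{hi}: only {len(ids)} C-alpha found"
        )
    return HelixTrace(
        helix_label=label,
        residue_ids=ids,
        points=np.array([by_res[r].coords for r in ids]),
        b_factors=np.array([by_res[r].b_factor for r in ids]),
        gaps=gaps,
    )


def kabsch_superpose(
    mobile: np.ndarray, reference: np.ndarray
) -> tuple[RigidTransform, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns the proper rigid transform (no reflection) minimizing the RMSD,
    and the minimized RMSD in nm.  Standard SVD solution of the orthogonal
    Procrustes problem with the determinant sign correction.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("point lists must be (n, 3) arrays of equal shape")
    if len(P) < 3:
        raise ValueError("need at least 3 points")
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    Pc, Qc = P - cp, Q - cq
    H = Pc.T @ Qc
    U, S, Vt = np.linalg.svd(H)
    # rank < 2 (all points collinear or coincident) leaves the rotation
    # about the degenerate axis undetermined
    if S[1] < 1e-12 * max(S[0], 1e-300):
        raise DegenerateGeometryError("degenerate (rank < 2) point configuration")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    moved = P @ R.T + t
    return RigidTransform(rotation=R, translation=t), rmsd(moved, Q)


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Root-mean-square distance between paired points (no superposition)."""
    A = np.asarray(a, dtype=float)
    B = np.asarray(b, dtype=float)
    if A.shape != B.shape:
        raise ValueError("point lists must have equal shape")
    if A.size == 0:
        raise ValueError("empty point lists")
    return float(np.sqrt(np.mean(np.sum((A - B) ** 2, axis=-1))))
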