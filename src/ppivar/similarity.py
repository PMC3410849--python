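"""Pairwise interface similarity between two hetero-dimers of one interaction.

Two dimers are first reduced to common residues: for identical sequences the
residue map is the identity, otherwise a global sequence alignment defines
it, restricted to aligned, non-gap positions resolved in both structures.
On the reduced structures three measures are computed:

* Face Position Similarity (fps): per side, the number of shared face
  positions divided by the geometric mean of the two face sizes; the two
  per-side values are combined by their arithmetic mean.  1 means the same
  residues form the interface, 0 means disjoint faces.
* L_rms: superpose the two larger chains ('receptors') on their common
  backbone, apply the transform to the smaller chains ('ligands'), and
  report the backbone RMSD of the ligands (the CAPRI ligand RMSD).
* I_rms: backbone RMSD over the interface region common to both dimers
  after superposing on exactly that region (the CAPRI interface RMSD).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.spatial.transform import Rotation

from .model import Chain, HeteroDimer

BACKBONE_ATOMS = ("N", "CA", "C", "O")
DEFAULT_MIN_COVERAGE = 0.3
MEASURES = ("fps", "l_rms", "i_rms")
#: Orientation of each measure: is larger more similar?
HIGHER_IS_BETTER = {"fps": True, "l_rms": False, "i_rms": False}


class SuperpositionError(ValueError):
    """Raised for degenerate point sets (fewer than 3 or collinear)."""


@dataclass
class ResidueCorrespondence:
    """Partial injective maps between SEQRES positions of matched chains."""

    mapX: dict[int, int]
    mapY: dict[int, int]
    coverage: float

    def side(self, which: str) -> dict[int, int]:
        return self.mapX if which == "X" else self.mapY


@dataclass
class SimilarityRecord:
    dimerA: str
    dimerB: str
    fps_X: float | None = None
    fps_Y: float | None = None
    fps: float | None = None
    l_rms: float | None = None
    i_rms: float | None = None
    level: str | None = None
    intra_assembly: bool = False

    def value(self, measure: str) -> float | None:
        return getattr(self, measure)


@lru_cache(maxsize=4096)
def _align_positions(seq_a: str, seq_b: str) -> tuple[tuple[int, int], ...]:
    """Aligned (1-based) position pairs from a global alignment."""
    if seq_a == seq_b:
        return tuple((i, i) for i in range(1, len(seq_a) + 1))
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    aln = aligner.align(seq_a, seq_b)[0]
    pairs: list[tuple[int, int]] = []
    for (qs, qe), (ts, te) in zip(*aln.aligned):
        pairs.extend((qs + k + 1, ts + k + 1) for k in range(qe - qs))
    return tuple(pairs)


def _side_map(chain_a: Chain, chain_b: Chain) -> dict[int, int]:
    resolved_a = chain_a.resolved_positions()
    resolved_b = chain_b.resolved_positions()
    return {
        pa: pb
        for pa, pb in _align_positions(chain_a.seqres, chain_b.seqres)
        if pa in resolved_a and pb in resolved_b
    }


def common_residues(
    dimer_a: HeteroDimer, dimer_b: HeteroDimer
) -> ResidueCorrespondence:
    """Common-residue reduction of two dimers with matched chain roles.

    Coverage is the fraction of the shorter sequence that is mapped and
    resolved in both structures, minimized over the two sides.
    """
    map_x = _side_map(dimer_a.chainX, dimer_b.chainX)
    map_y = _side_map(dimer_a.chainY, dimer_b.chainY)
    cov_x = len(map_x) / min(len(dimer_a.chainX.seqres), len(dimer_b.chainX.seqres))
    cov_y = len(map_y) / min(len(dimer_a.chainY.seqres), len(dimer_b.chainY.seqres))
    return ResidueCorrespondence(map_x, map_y, min(cov_x, cov_y))


def face_position_similarity(
    face_a: set[int] | tuple[int, ...],
    face_b: set[int] | tuple[int, ...],
    side_map: dict[int, int],
) -> float | None:
    """Shared face positions over the geometric mean of the face sizes.

    Faces are restricted to the common residues first.  Returns None when
    either face is empty after the reduction (similarity undefined).
    """
    face_a = set(face_a) & set(side_map)
    mapped_b = set(side_map.values())
    face_b = set(face_b) & mapped_b
    if not face_a or not face_b:
        return None
    shared = sum(1 for p in face_a if side_map[p] in face_b)
    return shared / math.sqrt(len(face_a) * len(face_b))


def combine_sides(fps_x: float, fps_y: float) -> float:
    """Arithmetic mean of the two per-side Face Position Similarities."""
    return 0.5 * (fps_x + fps_y)


def kabsch_superpose(
    coords_a: np.ndarray, coords_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of B onto A.

    Returns (R, t, rmsd) with a proper rotation R (no reflection) such that
    ``R @ b + t`` best matches ``a``; rmsd is the minimized RMSD.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise SuperpositionError("point sets must be matching N x 3 arrays")
    n = a.shape[0]
    if n < 3:
        raise SuperpositionError("need at least 3 paired points")
    cen_a, cen_b = a.mean(axis=0), b.mean(axis=0)
    if (
        np.linalg.matrix_rank(a - cen_a, tol=1e-8) < 2
        or np.linalg.matrix_rank(b - cen_b, tol=1e-8) < 2
    ):
        raise SuperpositionError("degenerate (collinear) point set")
    rot, rssd = Rotation.align_vectors(a - cen_a, b - cen_b)
    matrix = rot.as_matrix()
    translation = cen_a - matrix @ cen_b
    return matrix, translation, float(rssd / math.sqrt(n))


def _paired_backbone(
    chain_a: Chain, chain_b: Chain, side_map: dict[int, int],
    positions_a: set[int] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Matched backbone coordinates over mapped residues.

    Uses N, CA, C, O where present in both residues; falls back to whatever
    backbone subset the two residues share (at least CA).
    """
    rows_a, rows_b = [], []
    for pa, pb in sorted(side_map.items()):
        if positions_a is not None and pa not in positions_a:
            continue
        res_a = chain_a.residue_at(pa)
        res_b = chain_b.residue_at(pb)
        if res_a is None or res_b is None:
            continue
        atoms_a = {at.name: at.coord for at in res_a.atoms}
        atoms_b = {at.name: at.coord for at in res_b.atoms}
        for name in BACKBONE_ATOMS:
            if name in atoms_a and name in atoms_b:
                rows_a.append(atoms_a[name])
                rows_b.append(atoms_b[name])
    return (
        np.array(rows_a, dtype=float).reshape(-1, 3),
        np.array(rows_b, dtype=float).reshape(-1, 3),
    )


def receptor_side(dimer: HeteroDimer) -> str:
    """'X' or 'Y': the larger chain is the receptor; ties break by the
    lexicographically smaller accession."""
    lx, ly = len(dimer.chainX.seqres), len(dimer.chainY.seqres)
    if lx != ly:
        return "X" if lx > ly else "Y"
    return "X" if dimer.accX <= dimer.accY else "Y"


def l_rms(
    dimer_a: HeteroDimer,
    dimer_b: HeteroDimer,
    corr: ResidueCorrespondence,
) -> float | None:
    """CAPRI ligand RMSD; None when the receptors share <3 usable residues."""
    rec = receptor_side(dimer_a)
    lig = "Y" if rec == "X" else "X"
    rec_a, _, _ = dimer_a.side(rec)
    rec_b, _, _ = dimer_b.side(rec)
    lig_a, _, _ = dimer_a.side(lig)
    lig_b, _, _ = dimer_b.side(lig)
    ra, rb = _paired_backbone(rec_a, rec_b, corr.side(rec))
    if len(ra) < 3:
        return None
    try:
        rot, trans, _ = kabsch_superpose(ra, rb)
    except SuperpositionError:
        return None
    la, lb = _paired_backbone(lig_a, lig_b, corr.side(lig))
    if len(la) == 0:
        return None
    moved = lb @ rot.T + trans
    return float(np.sqrt(np.mean(np.sum((la - moved) ** 2, axis=1))))


def i_rms(
    dimer_a: HeteroDimer,
    dimer_b: HeteroDimer,
    corr: ResidueCorrespondence,
) -> float | None:
    """CAPRI interface RMSD over the interface region common to both dimers.

    The region is, per side, every mapped position that belongs to either
    dimer's face; both chains are superposed jointly on that region.
    """
    rows_a, rows_b = [], []
    n_res = 0
    for side in ("X", "Y"):
        side_map = corr.side(side)
        face_a = set(dimer_a.interface.face(side))
        face_b_back = {
            pa for pa, pb in side_map.items()
            if pb in set(dimer_b.interface.face(side))
        }
        region = (face_a | face_b_back) & set(side_map)
        n_res += len(region)
        ca, _, _ = dimer_a.side(side)
        cb, _, _ = dimer_b.side(side)
        pa_coords, pb_coords = _paired_backbone(ca, cb, side_map, region)
        rows_a.append(pa_coords)
        rows_b.append(pb_coords)
    if n_res < 3:
        return None
    a = np.vstack(rows_a)
    b = np.vstack(rows_b)
    if len(a) < 3:
        return None
    try:
        _, _, rmsd = kabsch_superpose(a, b)
    except SuperpositionError:
        return None
    return rmsd


def _oriented(dimer: HeteroDimer, swap: bool) -> HeteroDimer:
    if not swap:
        return dimer
    flipped = HeteroDimer(
        assembly_id=dimer.assembly_id,
        chainX=dimer.chainY, chainY=dimer.chainX,
        accX=dimer.accY, accY=dimer.accX,
        famX=dimer.famY, famY=dimer.famX,
        copy_number=dimer.copy_number,
    )
    if dimer.interface is not None:
        from .annotation import InterfaceAnnotation, ResiduePairAnnotation

        flipped.interface = InterfaceAnnotation(
            frozenset(
                ResiduePairAnnotation(
                    posX=p.posY, posY=p.posX, d=p.d,
                    dasa_X=p.dasa_Y, dasa_Y=p.dasa_X, rule=p.rule,
                )
                for p in dimer.interface.pairs
            )
        )
    return flipped


def _chain_roles_ambiguous(dimer_a: HeteroDimer, dimer_b: HeteroDimer) -> bool:
    """True when the X/Y roles of B cannot be fixed by accession or family."""
    if {dimer_a.accX, dimer_a.accY} == {dimer_b.accX, dimer_b.accY}:
        return False
    if dimer_a.famX != dimer_a.famY and {dimer_a.famX, dimer_a.famY} == {
        dimer_b.famX,
        dimer_b.famY,
    }:
        return False
    return dimer_a.fam_pair == dimer_b.fam_pair and dimer_a.famX == dimer_a.famY


def _role_matched(dimer_a: HeteroDimer, dimer_b: HeteroDimer) -> HeteroDimer:
    """Return B with chain roles matched to A (accession, then family)."""
    if dimer_a.accX == dimer_b.accX or dimer_a.accY == dimer_b.accY:
        return dimer_b
    if {dimer_a.accX, dimer_a.accY} == {dimer_b.accX, dimer_b.accY}:
        return _oriented(dimer_b, swap=True)
    if dimer_a.famX == dimer_b.famX or dimer_a.famY == dimer_b.famY:
        return dimer_b
    if {dimer_a.famX, dimer_a.famY} == {dimer_b.famX, dimer_b.famY}:
        return _oriented(dimer_b, swap=True)
    return dimer_b


def similarity_record(
    dimer_a: HeteroDimer,
    dimer_b: HeteroDimer,
    measures: tuple[str, ...] = MEASURES,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
) -> SimilarityRecord | None:
    """Compute all requested measures between two annotated dimers.

    Returns None when the common-residue coverage is below the floor or the
    faces vanish after reduction (comparison undefined).  When both dimers
    join two proteins of one family (so the chain roles are ambiguous) both
    orientations are evaluated and the more similar one by fps is kept.
    """
    if dimer_a.interface is None or dimer_b.interface is None:
        raise ValueError("dimers must be annotated before comparison")
    candidates = [_role_matched(dimer_a, dimer_b)]
    if _chain_roles_ambiguous(dimer_a, dimer_b):
        candidates.append(_oriented(candidates[0], swap=True))
    best: SimilarityRecord | None = None
    for cand in candidates:
        corr = common_residues(dimer_a, cand)
        if corr.coverage < min_coverage:
            continue
        fx = face_position_similarity(
            dimer_a.interface.faceX, cand.interface.faceX, corr.mapX
        )
        fy = face_position_similarity(
            dimer_a.interface.faceY, cand.interface.faceY, corr.mapY
        )
        if fx is None or fy is None:
            continue
        rec = SimilarityRecord(
            dimerA=dimer_a.uid,
            dimerB=dimer_b.uid,
            fps_X=fx,
            fps_Y=fy,
            fps=combine_sides(fx, fy),
            intra_assembly=dimer_a.assembly_id == dimer_b.assembly_id,
        )
        if "l_rms" in measures:
            rec.l_rms = l_rms(dimer_a, cand, corr)
        if "i_rms" in measures:
            rec.i_rms = i_rms(dimer_a, cand, corr)
        if best is None or (rec.fps is not None and rec.fps > (best.fps or -1)):
            best = rec
    return best
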