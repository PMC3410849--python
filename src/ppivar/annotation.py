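"""Interface annotation: which residue pairs of a hetero-dimer touch.

A residue pair (Rx, Ry) belongs to the interface if

(a) the two residues have at least one atom pair closer than the distance
    cutoff (default 6 A), or
(b) all of: both residues lose accessible surface area upon binding
    (dASA > 0), Rx has no partner on the other chain within the cutoff, and
    Ry is the closest dASA-positive residue of the other chain to Rx.

Rule (b) recovers contacts that fall slightly above the distance threshold
but clearly bury surface; it is evaluated in both directions and the two
pair sets are merged, which keeps the annotation symmetric.  Each admitted
pair carries two descriptors: d, the minimal inter-atomic distance, and the
dASA of both residues.

dASA is the classical ASA difference: the accessible surface area of each
chain computed alone (binding partner replaced by solvent) minus its ASA in
the dimer context.  ASA uses the Shrake-Rupley rolling-probe quadrature as
implemented in biotite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

import biotite.structure as bst
from biotite.structure.info import vdw_radius_single

from .model import Chain, HeteroDimer

DEFAULT_DISTANCE_CUTOFF = 6.0   # A, rule (a)
DEFAULT_MIN_FACE_SIZE = 5       # residues per face
DASA_NOISE_FLOOR = 0.1          # A^2, quadrature noise floor for "dASA > 0"
RULE_B_REACH = 12.0             # A, search radius for rule-(b) candidates;
                                # occlusion beyond ~9 A is geometrically impossible
DEFAULT_N_POINTS = 960
DEFAULT_PROBE_RADIUS = 1.4
DEFAULT_VDW_RADIUS = 1.8        # fallback for elements without tabulated radius


@dataclass
class AnnotationConfig:
    """Tunable parameters of the interface definition."""

    distance_cutoff: float = DEFAULT_DISTANCE_CUTOFF
    use_dasa: bool = True
    bidirectional: bool = True  # evaluate rule (b) in both directions
    dasa_threshold: float = DASA_NOISE_FLOOR
    probe_radius: float = DEFAULT_PROBE_RADIUS
    n_points: int = DEFAULT_N_POINTS
    min_face_size: int = DEFAULT_MIN_FACE_SIZE


@dataclass(frozen=True)
class ResiduePairAnnotation:
    posX: int
    posY: int
    d: float
    dasa_X: float
    dasa_Y: float
    rule: str  # 'distance' or 'dasa'


@dataclass
class InterfaceAnnotation:
    pairs: frozenset[ResiduePairAnnotation]
    faceX: tuple[int, ...] = field(init=False)
    faceY: tuple[int, ...] = field(init=False)

    def __post_init__(self) -> None:
        self.faceX = tuple(sorted({p.posX for p in self.pairs}))
        self.faceY = tuple(sorted({p.posY for p in self.pairs}))

    def face(self, side: str) -> tuple[int, ...]:
        return self.faceX if side == "X" else self.faceY


class AnnotationError(ValueError):
    """Raised when a chain has no resolved atoms to annotate."""


def _chain_atom_array(chains: list[Chain]) -> bst.AtomArray:
    rows = [
        (c.chain_id, r.seqres_index, r.name, a.name, a.element, a.coord)
        for c in chains
        for r in c.resolved_residues()
        for a in r.atoms
    ]
    array = bst.AtomArray(len(rows))
    for i, (cid, rid, rname, aname, elem, coord) in enumerate(rows):
        array.coord[i] = coord
        array.chain_id[i] = cid
        array.res_id[i] = rid
        array.res_name[i] = rname
        array.atom_name[i] = aname
        array.element[i] = elem.upper()
        array.hetero[i] = False
    return array


def _radii(array: bst.AtomArray) -> np.ndarray:
    radii = np.empty(array.array_length())
    unknown: set[str] = set()
    for i, elem in enumerate(array.element):
        r = vdw_radius_single(elem)
        if r is None:
            unknown.add(elem)
            r = DEFAULT_VDW_RADIUS
        radii[i] = r
    if unknown:
        warnings.warn(
            f"no van der Waals radius for element(s) {sorted(unknown)}; "
            f"using {DEFAULT_VDW_RADIUS} A"
        )
    return radii


def _per_residue_asa(
    chains: list[Chain], probe_radius: float, n_points: int
) -> dict[tuple[str, int], float]:
    """Shrake-Rupley ASA per residue, keyed by (chain_id, seqres position)."""
    array = _chain_atom_array(chains)
    if array.array_length() == 0:
        raise AnnotationError("no resolved atoms")
    atom_asa = bst.sasa(
        array,
        probe_radius=probe_radius,
        point_number=n_points,
        vdw_radii=_radii(array),
    )
    out: dict[tuple[str, int], float] = {}
    for cid, rid, a in zip(array.chain_id, array.res_id, atom_asa):
        if np.isnan(a):
            continue
        key = (str(cid), int(rid))
        out[key] = out.get(key, 0.0) + float(a)
    return out


def residue_asa(
    chain: Chain,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
) -> dict[int, float]:
    """ASA in A^2 per resolved residue of a single chain in isolation."""
    asa = _per_residue_asa([chain], probe_radius, n_points)
    return {pos: val for (_, pos), val in asa.items()}


def delta_asa(
    dimer: HeteroDimer,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
) -> tuple[dict[int, float], dict[int, float]]:
    """Per-residue ASA change upon binding for both chains of a dimer.

    dASA(residue) = ASA(chain alone) - ASA(chain in the dimer); tiny
    negative quadrature residuals are clamped to zero.
    """
    cx, cy = dimer.chainX, dimer.chainY
    together = _per_residue_asa([cx, cy], probe_radius, n_points)
    out = []
    for chain in (cx, cy):
        alone = residue_asa(chain, probe_radius, n_points)
        dasa = {}
        for pos, free in alone.items():
            bound = together.get((chain.chain_id, pos), 0.0)
            dasa[pos] = max(0.0, free - bound)
        out.append(dasa)
    return out[0], out[1]


def residue_pair_distances(
    chain_a: Chain, chain_b: Chain, reach: float = RULE_B_REACH
) -> dict[tuple[int, int], float]:
    """Minimal inter-atomic distance per inter-chain residue pair, for all
    pairs with at least one atom pair below ``reach``."""
    ca, cb = chain_a.atom_coords(), chain_b.atom_coords()
    if len(ca) == 0 or len(cb) == 0:
        raise AnnotationError("chain without resolved atoms")
    ra, rb = chain_a.atom_residue_index(), chain_b.atom_residue_index()
    sparse = cKDTree(ca).sparse_distance_matrix(
        cKDTree(cb), reach, output_type="coo_matrix"
    )
    dists: dict[tuple[int, int], float] = {}
    for i, j, d in zip(sparse.row, sparse.col, sparse.data):
        key = (int(ra[i]), int(rb[j]))
        if d < dists.get(key, np.inf):
            dists[key] = float(d)
    return dists


def _rule_b_pairs(
    dists: dict[tuple[int, int], float],
    dasa_x: dict[int, float],
    dasa_y: dict[int, float],
    cutoff: float,
    threshold: float,
    transpose: bool,
) -> set[tuple[int, int]]:
    """One direction of rule (b); ``transpose`` flips the pair orientation
    of ``dists`` so the same code serves X->Y and Y->X."""
    if transpose:
        dists = {(y, x): d for (x, y), d in dists.items()}
    has_close_partner = {x for (x, _), d in dists.items() if d < cutoff}
    pairs: set[tuple[int, int]] = set()
    for rx, dx in dasa_x.items():
        if dx <= threshold or rx in has_close_partner:
            continue
        candidates = [
            (d, ry)
            for (x, ry), d in dists.items()
            if x == rx and dasa_y.get(ry, 0.0) > threshold
        ]
        if not candidates:
            continue
        _, ry = min(candidates)
        pairs.add((rx, ry))
    return {(y, x) for x, y in pairs} if transpose else pairs


def annotate_interface(
    dimer: HeteroDimer, config: AnnotationConfig | None = None
) -> InterfaceAnnotation:
    """Annotate all interacting residue pairs of a hetero-dimer."""
    config = config or AnnotationConfig()
    reach = max(RULE_B_REACH, config.distance_cutoff)
    dists = residue_pair_distances(dimer.chainX, dimer.chainY, reach)
    if config.use_dasa:
        dasa_x, dasa_y = delta_asa(dimer, config.probe_radius, config.n_points)
    else:
        dasa_x, dasa_y = {}, {}
    admitted: dict[tuple[int, int], str] = {}
    for key, d in dists.items():
        if d < config.distance_cutoff:
            admitted[key] = "distance"
    if config.use_dasa:
        extra = _rule_b_pairs(
            dists, dasa_x, dasa_y, config.distance_cutoff,
            config.dasa_threshold, transpose=False,
        )
        if config.bidirectional:
            extra |= _rule_b_pairs(
                dists, dasa_y, dasa_x, config.distance_cutoff,
                config.dasa_threshold, transpose=True,
            )
        for key in extra:
            admitted.setdefault(key, "dasa")
    pairs = frozenset(
        ResiduePairAnnotation(
            posX=x,
            posY=y,
            d=dists[(x, y)],
            dasa_X=dasa_x.get(x, 0.0),
            dasa_Y=dasa_y.get(y, 0.0),
            rule=rule,
        )
        for (x, y), rule in admitted.items()
    )
    return InterfaceAnnotation(pairs)


def passes_size_filter(
    annotation: InterfaceAnnotation, min_face_size: int = DEFAULT_MIN_FACE_SIZE
) -> bool:
    """True iff both faces have at least ``min_face_size`` residues."""
    return (
        len(annotation.faceX) >= min_face_size
        and len(annotation.faceY) >= min_face_size
    )


def assign_copy_numbers(dimers: list[HeteroDimer]) -> None:
    """Set the interface copy number on every dimer of one assembly.

    The copy number of a dimer is the number of dimers extracted from the
    same assembly (itself included) with exactly the same unordered pair of
    SEQRES sequences.
    """
    assemblies = {d.assembly_id for d in dimers}
    if len(assemblies) > 1:
        raise ValueError("copy numbers are defined within a single assembly")
    counts: dict[tuple[str, str], int] = {}
    for d in dimers:
        counts[d.seq_pair] = counts.get(d.seq_pair, 0) + 1
    for d in dimers:
        d.copy_number = counts[d.seq_pair]


def annotation_rows(dimer: HeteroDimer) -> list[dict]:
    """Flat per-pair records for TSV serialization."""
    rows = []
    for p in sorted(dimer.interface.pairs, key=lambda p: (p.posX, p.posY)):
        rows.append(
            {
                "assembly_id": dimer.assembly_id,
                "chainX": dimer.chainX.chain_id,
                "chainY": dimer.chainY.chain_id,
                "posX": p.posX,
                "posY": p.posY,
                "d": round(p.d, 3),
                "dASA_X": round(p.dasa_X, 3),
                "dASA_Y": round(p.dasa_Y, 3),
                "rule": p.rule,
            }
        )
    return rows
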