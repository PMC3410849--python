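"""Synthetic biological assemblies with known interface ground truth.

The generator builds idealized rod-like protein chains (N, CA, C, O, CB
backbone along a straight, twisted axis; consecutive CA-CA = 3.8 A) and
docks them pairwise so that a designated sequence window on each side forms
the interface.  A family's distinct *binding modes* use disjoint windows,
so two dimers in the same mode have Face Position Similarity 1 and two
dimers in different modes share (essentially) no face residues.

The statistical model mirrors how repeated structure determinations sample
binding modes:

* each single-copy assembly draws its mode independently from the planted
  mode mixture, so for two observations the chance of a cross-mode
  comparison is 1 - sum(q_i^2) (= 2 p (1-p) for two modes);
* an assembly with k interface copies places its copies on successive
  alternative sites (mode m, m+1, ...), the packing motif by which one
  partner binds a multimer at several positions -- so higher copy numbers
  raise the fraction of cross-mode comparisons;
* with some probability an assembly embeds the partner twice via an
  explicit homo-dimer bridge (two X chains in contact, one Y touching
  both), the topology targeted by homomer best-match filtering;
* optionally a world includes an alpha3-beta3-gamma ring: two same-family
  proteins alternating around a central chain of another family, the
  'structural homomer' scenario.

Everything is deterministic given the world seed; each emitted interface
has one ground-truth row, and closed-form expectations for the cross-mode
comparison fraction are provided for the regular (non-homomer, non-ring)
blocks.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .model import AA1_TO_3, Assembly, Atom, Chain, ProteinMapping, Residue
from .structures import write_assembly, write_mapping

#: amino-acid alphabet for synthetic sequences; glycine is excluded so every
#: residue can carry a CB atom.
ALPHABET = "ACDEFHIKLMNPQRSTVWY"

CA_STEP = 3.8          # A between consecutive CA atoms
TWIST_PER_RESIDUE = math.radians(100.0)
DOCK_GAP = 5.4         # A between the two chain axes at the contact point
DOCK_ANGLE = math.radians(25.0)  # crossing angle between docked rod axes
RING_RADIUS = 5.0      # A, ring-chain axis distance from the central axis
RING_STAGGER = 40.0    # A, vertical offset between successive ring chains
RING_CHAIN_LENGTH = 30
RING_CORE_LENGTH = 90
DEFAULT_CHAIN_LENGTH = 60
WINDOW_HALF_WIDTH = 4  # residues; designated patch = center +/- 4 (>= 8 res)


@dataclass
class WorldSpec:
    """Parameters of one synthetic world.

    ``mode_mixture`` is the probability of each binding mode for an
    independent observation; ``copy_number_dist`` maps interface copy
    numbers (1..6) to probabilities; ``homomer_rate`` is the chance that an
    observation embeds the complex as the homo-dimer-bridge topology;
    ``mutation_rate`` / ``family_divergence`` are the per-residue
    substitution probabilities for same-protein variants and for family
    homologs (which keep the backbone).
    """

    n_families: int = 4
    prots_per_family: int = 2
    seqs_per_prot: int = 2
    obs_per_seq: int = 3
    modes_per_pair: int = 2
    mode_mixture: tuple[float, ...] = (0.8, 0.2)
    copy_number_dist: dict[int, float] = field(
        default_factory=lambda: {1: 0.7, 2: 0.2, 3: 0.1}
    )
    homomer_rate: float = 0.2
    mutation_rate: float = 0.03
    family_divergence: float = 0.4
    chain_length: int = DEFAULT_CHAIN_LENGTH
    include_ring: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.mode_mixture) != self.modes_per_pair:
            raise ValueError("mode_mixture length must equal modes_per_pair")
        if not math.isclose(sum(self.mode_mixture), 1.0, abs_tol=1e-9):
            raise ValueError("mode_mixture must sum to 1")
        if not math.isclose(sum(self.copy_number_dist.values()), 1.0, abs_tol=1e-9):
            raise ValueError("copy_number_dist must sum to 1")
        if not all(1 <= k <= 6 for k in self.copy_number_dist):
            raise ValueError("copy numbers must be in 1..6")
        if not 0 <= self.homomer_rate <= 1:
            raise ValueError("homomer_rate must be a probability")


@dataclass
class TruthRow:
    assembly_id: str
    chain_x: str
    chain_y: str
    mode_label: int
    copy_number: int
    homomer_context: bool
    ring_context: bool = False


@dataclass
class World:
    spec: WorldSpec
    assemblies: list[Assembly]
    mapping: ProteinMapping
    truth: list[TruthRow]
    expected: dict[str, float]


# ---------------------------------------------------------------------------
# chain construction and placement


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(ALPHABET), size=length))


def build_chain(
    length: int,
    fold_seed: int = 0,
    sequence: str | None = None,
    chain_id: str = "A",
) -> Chain:
    """An idealized rod chain along +x with N, CA, C, O, CB per residue.

    The backbone twists around the axis (100 degrees per residue, phase set
    by ``fold_seed``), so the atom cloud is fully 3-dimensional although
    the CA trace is straight.  Deterministic given its arguments.
    """
    if length < 30:
        raise ValueError("chains must have at least 30 residues")
    rng = np.random.default_rng(fold_seed)
    phase = float(rng.uniform(0, 2 * math.pi))
    if sequence is None:
        sequence = _random_sequence(rng, length)
    if len(sequence) != length:
        raise ValueError("sequence length mismatch")
    residues = []
    for i in range(length):
        w = TWIST_PER_RESIDUE * i + phase
        ca = np.array([CA_STEP * i, 0.0, 0.0])

        def ring_offset(dx: float, r: float, dw: float) -> np.ndarray:
            return np.array(
                [dx, r * math.cos(w + dw), r * math.sin(w + dw)]
            )

        atoms = [
            Atom("N", "N", ca + ring_offset(-1.20, 0.80, 0.0)),
            Atom("CA", "C", ca),
            Atom("C", "C", ca + ring_offset(1.20, 0.70, 2.1)),
            Atom("O", "O", ca + ring_offset(1.45, 1.10, 2.8)),
            Atom("CB", "C", ca + ring_offset(0.0, 1.50, 4.4)),
        ]
        residues.append(Residue(i + 1, str(i + 1), AA1_TO_3[sequence[i]], atoms))
    return Chain(chain_id, sequence, residues)


def _rotation(direction: np.ndarray, up: np.ndarray) -> np.ndarray:
    """Rotation matrix sending x to ``direction`` (z near ``up``)."""
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    u = np.asarray(up, float)
    u = u - np.dot(u, d) * d
    norm = np.linalg.norm(u)
    if norm < 1e-9:
        raise ValueError("up vector parallel to direction")
    u /= norm
    return np.column_stack([d, np.cross(u, d) * -1.0, u])


def place_chain(
    chain: Chain,
    anchor_index: int,
    point,
    direction,
    up=(0.0, 0.0, 1.0),
    chain_id: str | None = None,
) -> Chain:
    """Rigidly place a template chain: CA of ``anchor_index`` (1-based) at
    ``point``, axis along ``direction``."""
    rot = _rotation(direction, up)
    anchor = np.array([CA_STEP * (anchor_index - 1), 0.0, 0.0])
    shift = np.asarray(point, float) - rot @ anchor
    return transform_chain(chain, rot, shift, chain_id=chain_id)


def transform_chain(
    chain: Chain, rot: np.ndarray, shift: np.ndarray, chain_id: str | None = None
) -> Chain:
    residues = [
        Residue(
            r.seqres_index,
            r.author_id,
            r.name,
            [Atom(a.name, a.element, rot @ a.coord + shift) for a in r.atoms],
        )
        for r in chain.residues
    ]
    return Chain(chain_id or chain.chain_id, chain.seqres, residues)


# ---------------------------------------------------------------------------
# binding modes and docking


@dataclass(frozen=True)
class BindingMode:
    """One binding mode: interface windows (1-based centers) on each side."""

    index: int
    center_x: int
    center_y: int

    def patch_x(self) -> set[int]:
        return set(
            range(self.center_x - WINDOW_HALF_WIDTH, self.center_x + WINDOW_HALF_WIDTH + 1)
        )

    def patch_y(self) -> set[int]:
        return set(
            range(self.center_y - WINDOW_HALF_WIDTH, self.center_y + WINDOW_HALF_WIDTH + 1)
        )


def binding_modes(length: int, n_modes: int) -> list[BindingMode]:
    """Evenly spaced, disjoint interface windows along the chains."""
    centers = [round(length * (j + 1) / (n_modes + 1)) for j in range(n_modes)]
    if any(b - a < 2 * WINDOW_HALF_WIDTH + 4 for a, b in zip(centers, centers[1:])):
        raise ValueError(f"chain of {length} residues too short for {n_modes} modes")
    return [BindingMode(j, c, c) for j, c in enumerate(centers)]


def dock(
    chain_x: Chain,
    chain_y: Chain,
    mode: BindingMode,
    ids: tuple[str, str] = ("A", "B"),
    origin=(0.0, 0.0, 0.0),
) -> tuple[Chain, Chain]:
    """Place two rod chains crossing at their mode windows.

    X runs along +x through ``origin``; Y crosses above it at the window
    center, tilted by the crossing angle, with the two axes ``DOCK_GAP``
    apart -- close enough that the window residues interact, far enough
    that no other residues do.
    """
    origin = np.asarray(origin, float)
    placed_x = place_chain(chain_x, mode.center_x, origin, (1, 0, 0), chain_id=ids[0])
    direction = (math.cos(DOCK_ANGLE), math.sin(DOCK_ANGLE), 0.0)
    placed_y = place_chain(
        chain_y,
        mode.center_y,
        origin + np.array([0.0, 0.0, DOCK_GAP]),
        direction,
        chain_id=ids[1],
    )
    return placed_x, placed_y


def homomer_complex(
    chain_x: Chain,
    chain_y: Chain,
    modes: tuple[BindingMode, BindingMode],
    ids: tuple[str, str, str] = ("A", "B", "C"),
) -> list[Chain]:
    """Two copies of X bound to one Y at different windows, with the X
    copies in contact: the homo-dimer-bridge topology of alternative
    binding to the same homomer.

    Chain order: X1, X2, Y.
    """
    m1, m2 = modes
    if m1.index == m2.index:
        raise ValueError("the two interfaces must use different modes")
    placed_y = place_chain(chain_y, 1, (0, 0, 0), (1, 0, 0), chain_id=ids[2])
    x1 = place_chain(
        chain_x,
        m1.center_x,
        (CA_STEP * (m1.center_y - 1), 0.0, DOCK_GAP),
        (math.cos(DOCK_ANGLE), math.sin(DOCK_ANGLE), 0.0),
        chain_id=ids[0],
    )
    # The second copy starts from the same dock geometry at its own window
    # (leaning the other way) and is swung around Y's axis until it touches
    # the first copy without clashing; rotating about the axis leaves the
    # X2-Y contact geometry unchanged.
    x2_flat = place_chain(
        chain_x,
        m2.center_x,
        (CA_STEP * (m2.center_y - 1), 0.0, DOCK_GAP),
        (math.cos(DOCK_ANGLE), -math.sin(DOCK_ANGLE), 0.0),
        chain_id=ids[1],
    )
    from .structures import min_interchain_distance

    chosen = None
    for phi_deg in range(10, 351, 5):
        phi = math.radians(phi_deg)
        rot = np.array(
            [
                [1.0, 0.0, 0.0],
                [0.0, math.cos(phi), -math.sin(phi)],
                [0.0, math.sin(phi), math.cos(phi)],
            ]
        )
        candidate = transform_chain(x2_flat, rot, np.zeros(3))
        dist = min_interchain_distance(x1, candidate)
        if 3.6 <= dist <= 5.6:
            chosen = candidate
            break
    if chosen is None:
        raise RuntimeError("could not place the second homomer copy")
    return [x1, chosen, placed_y]


def ring_complex(
    alpha: Chain,
    beta: Chain,
    core: Chain,
    rotation_steps: int = 0,
) -> list[Chain]:
    """An alternating alpha/beta hexameric ring around a central core chain.

    Ring chains are vertical rods on a circle, each offset in height, so
    every subunit touches the core at a different region; adjacent ring
    chains are in contact, closing the (structural) homomer over the ring.
    ``rotation_steps`` rotates the height assignment by ring positions
    (use multiples of 2 to keep alpha positions on alpha chains).
    """
    chains = []
    ring_ids = ["A", "B", "C", "D", "E", "F"]
    for pos in range(6):
        template = alpha if pos % 2 == 0 else beta
        psi = math.radians(60.0 * pos)
        height = RING_STAGGER * ((pos + rotation_steps) % 6)
        placed = place_chain(
            template,
            1,
            (RING_RADIUS * math.cos(psi), RING_RADIUS * math.sin(psi), height),
            (0, 0, 1),
            up=(math.cos(psi), math.sin(psi), 0),
            chain_id=ring_ids[pos],
        )
        chains.append(placed)
    chains.append(place_chain(core, 1, (0, 0, 0), (0, 0, 1),
                              up=(1, 0, 0), chain_id="G"))
    return chains


# ---------------------------------------------------------------------------
# sequence variants


def make_variants(
    chain: Chain,
    kind: str,
    rate: float,
    seed: int,
) -> Chain:
    """A sequence variant of a chain with identical backbone coordinates.

    kind='point_mutation' emulates engineered or natural single-residue
    variants of the same protein; kind='family_divergence' emulates a
    family homolog whose fold (backbone) is preserved.  Both substitute
    each residue independently with probability ``rate``.
    """
    if kind not in ("point_mutation", "family_divergence"):
        raise ValueError(f"unknown variant kind {kind!r}")
    if not 0 <= rate < 1:
        raise ValueError("rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    new_seq = []
    for aa in chain.seqres:
        if rng.random() < rate:
            options = [c for c in ALPHABET if c != aa]
            new_seq.append(options[int(rng.integers(len(options)))])
        else:
            new_seq.append(aa)
    new_seq = "".join(new_seq)
    residues = [
        Residue(
            r.seqres_index, r.author_id, AA1_TO_3[new_seq[r.seqres_index - 1]],
            [Atom(a.name, a.element, a.coord.copy()) for a in r.atoms],
        )
        for r in chain.residues
    ]
    return Chain(chain.chain_id, new_seq, residues)


# ---------------------------------------------------------------------------
# closed-form expectations


def _mode_difference_distribution(mixture: tuple[float, ...]) -> list[float]:
    """P((m - m') mod M = d) for independent draws m, m' from the mixture."""
    m = len(mixture)
    return [
        sum(mixture[i] * mixture[(i - d) % m] for i in range(m)) for d in range(m)
    ]


def expected_cross_fraction_for_copies(
    copies: list[int], mixture: tuple[float, ...]
) -> float:
    """Expected fraction of cross-mode pairs among all pairwise comparisons
    of one sequence-identical group whose assemblies have the given copy
    numbers.

    Copies within one assembly sit on successive modes (m, m+1, ...); the
    base mode of each assembly is an independent mixture draw.
    """
    m = len(mixture)
    diff = _mode_difference_distribution(mixture)
    members = [(a, j) for a, k in enumerate(copies) for j in range(k)]
    total, cross = 0, 0.0
    for (a, j), (b, l) in itertools.combinations(members, 2):
        total += 1
        if a == b:
            cross += 1.0 if (j - l) % m != 0 else 0.0
        else:
            cross += 1.0 - diff[(l - j) % m]
    return cross / total if total else 0.0


def expected_cross_fraction(
    n_assemblies: int,
    copy_number_dist: dict[int, float],
    mixture: tuple[float, ...],
    seed: int = 0,
    n_samples: int = 20000,
) -> float:
    """Expected cross-mode comparison fraction of a sequence-identical
    group, averaged over the copy-number distribution.

    Exhaustive over all copy-number assignments when feasible, otherwise a
    seeded Monte Carlo average.
    """
    support = sorted(copy_number_dist)
    if len(support) == 1:
        return expected_cross_fraction_for_copies(
            [support[0]] * n_assemblies, mixture
        )
    n_combos = len(support) ** n_assemblies
    if n_combos <= 5000:
        value = 0.0
        for combo in itertools.product(support, repeat=n_assemblies):
            weight = math.prod(copy_number_dist[k] for k in combo)
            value += weight * expected_cross_fraction_for_copies(list(combo), mixture)
        return value
    rng = np.random.default_rng(seed)
    probs = [copy_number_dist[k] for k in support]
    draws = rng.choice(support, size=(n_samples, n_assemblies), p=probs)
    return float(
        np.mean(
            [
                expected_cross_fraction_for_copies(list(row), mixture)
                for row in draws
            ]
        )
    )


# ---------------------------------------------------------------------------
# world generation


def _assembly_chain_ids(n: int) -> list[str]:
    return [chr(ord("A") + i) for i in range(n)]


def generate_world(spec: WorldSpec, out_dir: str | Path | None = None) -> World:
    """Generate a full synthetic world; optionally write it to ``out_dir``
    as PDB files plus mapping, truth and manifest files."""
    rng = np.random.default_rng(spec.seed)
    modes = binding_modes(spec.chain_length, spec.modes_per_pair)
    mixture = np.asarray(spec.mode_mixture)
    copy_support = sorted(spec.copy_number_dist)
    copy_probs = [spec.copy_number_dist[k] for k in copy_support]

    assemblies: list[Assembly] = []
    mapping = ProteinMapping()
    truth: list[TruthRow] = []
    counter = itertools.count()

    for fam in range(spec.n_families):
        fam_a, fam_b = f"FA{fam:02d}", f"FB{fam:02d}"
        base_x = build_chain(spec.chain_length, fold_seed=spec.seed * 997 + fam * 2)
        base_y = build_chain(
            spec.chain_length, fold_seed=spec.seed * 997 + fam * 2 + 1
        )
        for prot in range(spec.prots_per_family):
            acc_x, acc_y = f"PX{fam:02d}{prot}", f"PY{fam:02d}{prot}"
            if prot == 0:
                prot_x, prot_y = base_x, base_y
            else:
                prot_x = make_variants(
                    base_x, "family_divergence", spec.family_divergence,
                    seed=spec.seed * 7919 + fam * 101 + prot * 2,
                )
                prot_y = make_variants(
                    base_y, "family_divergence", spec.family_divergence,
                    seed=spec.seed * 7919 + fam * 101 + prot * 2 + 1,
                )
            for variant in range(spec.seqs_per_prot):
                if variant == 0:
                    var_x = prot_x
                else:
                    var_x = make_variants(
                        prot_x, "point_mutation", spec.mutation_rate,
                        seed=spec.seed * 6007 + fam * 211 + prot * 17 + variant,
                    )
                for _ in range(spec.obs_per_seq):
                    aid = f"w{spec.seed}-a{next(counter):03d}"
                    base_mode = int(rng.choice(spec.modes_per_pair, p=mixture))
                    as_homomer = (
                        spec.modes_per_pair >= 2 and rng.random() < spec.homomer_rate
                    )
                    if as_homomer:
                        pair = (
                            modes[base_mode],
                            modes[(base_mode + 1) % spec.modes_per_pair],
                        )
                        chains = homomer_complex(var_x, prot_y, pair)
                        assembly = Assembly(aid, chains, resolution=1.9)
                        for cid in ("A", "B"):
                            mapping.add(aid, cid, acc_x, fam_a)
                        mapping.add(aid, "C", acc_y, fam_b)
                        for cid, mode in zip(("A", "B"), pair):
                            truth.append(
                                TruthRow(aid, cid, "C", mode.index, 2, True)
                            )
                    else:
                        k = int(rng.choice(copy_support, p=copy_probs))
                        ids = _assembly_chain_ids(2 * k)
                        chains = []
                        for copy in range(k):
                            mode = modes[(base_mode + copy) % spec.modes_per_pair]
                            cx, cy = dock(
                                var_x,
                                prot_y,
                                mode,
                                ids=(ids[2 * copy], ids[2 * copy + 1]),
                                origin=(0.0, 0.0, 300.0 * copy),
                            )
                            chains.extend([cx, cy])
                            truth.append(
                                TruthRow(
                                    aid, ids[2 * copy], ids[2 * copy + 1],
                                    mode.index, k, False,
                                )
                            )
                        assembly = Assembly(aid, chains, resolution=1.9)
                        for copy in range(k):
                            mapping.add(aid, ids[2 * copy], acc_x, fam_a)
                            mapping.add(aid, ids[2 * copy + 1], acc_y, fam_b)
                    assemblies.append(assembly)

    if spec.include_ring:
        ring_seed = spec.seed * 4409 + 1
        alpha = build_chain(RING_CHAIN_LENGTH, fold_seed=ring_seed)
        beta = make_variants(
            alpha, "family_divergence", spec.family_divergence, seed=ring_seed + 1
        )
        core = build_chain(RING_CORE_LENGTH, fold_seed=ring_seed + 2)
        for obs, rotation in enumerate((0, 2)):
            aid = f"w{spec.seed}-ring{obs}"
            chains = ring_complex(alpha, beta, core, rotation_steps=rotation)
            assemblies.append(Assembly(aid, chains, resolution=1.9))
            for pos, cid in enumerate("ABCDEF"):
                acc = "PRALPHA" if pos % 2 == 0 else "PRBETA"
                mapping.add(aid, cid, acc, "FRING")
                truth.append(
                    TruthRow(
                        aid, cid, "G",
                        mode_label=(pos + rotation) % 6,
                        copy_number=3,
                        homomer_context=False,
                        ring_context=True,
                    )
                )
            mapping.add(aid, "G", "PRCORE", "FCORE")

    expected = {
        "cross_mode_fraction": expected_cross_fraction(
            spec.obs_per_seq, spec.copy_number_dist, spec.mode_mixture,
            seed=spec.seed,
        ),
        "cross_mode_fraction_copy1": expected_cross_fraction(
            spec.obs_per_seq, {1: 1.0}, spec.mode_mixture
        ),
    }
    world = World(spec, assemblies, mapping, truth, expected)
    if out_dir is not None:
        write_world(world, out_dir)
    return world


def write_world(world: World, out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    structures = out_dir / "structures"
    structures.mkdir(exist_ok=True)
    for assembly in world.assemblies:
        write_assembly(assembly, structures / f"{assembly.assembly_id}.pdb")
    write_mapping(world.mapping, out_dir / "mapping.tsv")
    header = (
        "assembly_id\tchain_x\tchain_y\tmode_label\tcopy_number\t"
        "homomer_context\tring_context"
    )
    lines = [header]
    for row in world.truth:
        lines.append(
            f"{row.assembly_id}\t{row.chain_x}\t{row.chain_y}\t{row.mode_label}"
            f"\t{row.copy_number}\t{int(row.homomer_context)}\t{int(row.ring_context)}"
        )
    (out_dir / "truth.tsv").write_text("\n".join(lines) + "\n")
    manifest = {
        "spec": {
            **{
                k: v
                for k, v in asdict(world.spec).items()
                if k != "copy_number_dist"
            },
            "copy_number_dist": {
                str(k): v for k, v in world.spec.copy_number_dist.items()
            },
        },
        "expected": world.expected,
        "n_assemblies": len(world.assemblies),
        "n_interfaces": len(world.truth),
    }
    (out_dir / "world.json").write_text(json.dumps(manifest, indent=2) + "\n")
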