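"""Reading and writing biological assemblies and chain-protein mapping tables.

Structure files are parsed with gemmi in both PDB and mmCIF dialects.
Residues are re-indexed onto the full deposited sequence (SEQRES) via
gemmi's label_seq assignment, so two entries of the same protein are
comparable even when their author numbering differs.

Entry selection follows the usual criteria for a high-resolution interaction
data set: X-ray structures below a resolution ceiling whose chains map to at
least two distinct protein accessions.  Candidate hetero-dimers are all
chain pairs with different accessions that have at least one inter-chain
atom pair below a contact cutoff (default 6 A).
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import gemmi
import numpy as np
from scipy.spatial import cKDTree

from .model import (
    AA1_TO_3,
    AA3_TO_1,
    Assembly,
    Atom,
    Chain,
    HeteroDimer,
    MappingEntry,
    ProteinMapping,
    Residue,
    canonical_chain_order,
)

log = logging.getLogger(__name__)

DEFAULT_CONTACT_CUTOFF = 6.0  # A; one atom pair closer than this = interacting
DEFAULT_MAX_RESOLUTION = 2.5  # A; strict upper bound for entry retention
MIN_CHAIN_LENGTH = 30         # residues; shorter chains are never mapped
MIN_IDENTITY_COVERAGE = 0.9   # fraction of the chain that must align


class StructureFormatError(ValueError):
    """Raised when a structure file cannot be parsed or has no protein chain."""


def _structure_to_assembly(st: gemmi.Structure, assembly_id: str) -> Assembly:
    st.setup_entities()
    st.assign_label_seq_id()
    chains: list[Chain] = []
    for gchain in st[0]:
        polymer = gchain.get_polymer()
        entity = st.get_entity_of(polymer)
        if entity is None or not entity.full_sequence:
            continue
        seqres = gemmi.one_letter_code(entity.full_sequence).upper()
        if not seqres or not all(c in AA1_TO_3 for c in seqres):
            continue
        residues: list[Residue] = []
        seen_pos: set[int] = set()
        for gres in gchain:
            if gres.name not in AA3_TO_1:
                continue  # waters, ligands, modified residues are dropped
            pos = gres.label_seq
            if pos is None or pos in seen_pos:
                continue
            seen_pos.add(pos)
            atoms = [
                Atom(a.name, a.element.name, np.array([a.pos.x, a.pos.y, a.pos.z]))
                for a in gres
                if a.element.name != "H"
            ]
            residues.append(
                Residue(pos, str(gres.seqid.num), gres.name, atoms)
            )
        # Unresolved SEQRES positions are represented as atom-less residues.
        for pos in range(1, len(seqres) + 1):
            if pos not in seen_pos:
                residues.append(Residue(pos, "", AA1_TO_3[seqres[pos - 1]], []))
        residues.sort(key=lambda r: r.seqres_index)
        chains.append(Chain(gchain.name, seqres, residues))
    if not chains:
        raise StructureFormatError(f"no protein chains in {assembly_id}")
    resolution = st.resolution if st.resolution and st.resolution > 0 else None
    try:
        method = st.info["_exptl.method"]
    except KeyError:
        method = ""
    return Assembly(assembly_id, chains, resolution=resolution, method=method)


def _cif_resolution(path: Path) -> float | None:
    block = gemmi.cif.read(str(path)).sole_block()
    for tag in ("_refine.ls_d_res_high", "_reflns.d_resolution_high"):
        val = block.find_value(tag)
        if val is not None:
            try:
                return float(val)
            except ValueError:
                continue
    return None


def load_assembly(path: str | Path, format: str | None = None) -> Assembly:
    """Load one biological assembly from a PDB or mmCIF file.

    ``format`` is 'pdb' or 'mmcif'; inferred from the suffix when omitted.
    The file stem is used as the assembly identifier.
    """
    path = Path(path)
    if format is None:
        format = "mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"
    try:
        if format == "pdb":
            st = gemmi.read_pdb(str(path))
        elif format == "mmcif":
            st = gemmi.make_structure_from_block(
                gemmi.cif.read(str(path)).sole_block()
            )
        else:
            raise ValueError(f"unknown format {format!r}")
    except (RuntimeError, ValueError) as exc:
        raise StructureFormatError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise StructureFormatError(f"no models in {path}")
    assembly = _structure_to_assembly(st, path.stem)
    if assembly.resolution is None and format == "mmcif":
        res = _cif_resolution(path)
        if res is not None and res > 0:
            assembly.resolution = res
    return assembly


def write_assembly(
    assembly: Assembly, path: str | Path, format: str | None = None
) -> None:
    """Write an assembly as PDB or mmCIF, including the full SEQRES."""
    path = Path(path)
    if format is None:
        format = "mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"
    st = gemmi.Structure()
    st.name = assembly.assembly_id
    st.spacegroup_hm = "P 1"
    st.cell = gemmi.UnitCell(1, 1, 1, 90, 90, 90)
    if assembly.resolution is not None:
        st.resolution = assembly.resolution
    st.info["_exptl.method"] = assembly.method or "X-RAY DIFFRACTION"
    model = gemmi.Model("1")
    for chain in assembly.chains:
        gchain = gemmi.Chain(chain.chain_id)
        for res in chain.residues:
            if not res.resolved:
                continue
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.seqres_index, " ")
            gres.label_seq = res.seqres_index
            for atom in res.atoms:
                gatom = gemmi.Atom()
                gatom.name = atom.name
                gatom.element = gemmi.Element(atom.element)
                gatom.pos = gemmi.Position(*atom.coord)
                gres.add_atom(gatom)
            gchain.add_residue(gres)
        model.add_chain(gchain)
    st.add_model(model)
    st.setup_entities()
    by_id = {c.chain_id: c for c in assembly.chains}
    for entity in st.entities:
        if entity.subchains:
            cid = entity.subchains[0].rstrip("xp")  # subchain names like 'Axp'
            src = by_id.get(cid) or by_id.get(entity.subchains[0][0])
            if src is None:
                continue
            entity.full_sequence = [AA1_TO_3[c] for c in src.seqres]
    if format == "pdb":
        path.write_text(st.make_pdb_string())
    elif format == "mmcif":
        block = st.make_mmcif_block()
        if assembly.resolution is not None:
            block.set_pair("_refine.ls_d_res_high", f"{assembly.resolution:.2f}")
        path.write_text(block.as_string())
    else:
        raise ValueError(f"unknown format {format!r}")


def passes_entry_filter(
    assembly: Assembly,
    mapping: ProteinMapping,
    max_resolution: float = DEFAULT_MAX_RESOLUTION,
    require_xray: bool = True,
) -> bool:
    """Entry retention: X-ray, resolution strictly below the ceiling, and
    chains mapping to at least two distinct accessions."""
    if require_xray and "X-RAY" not in (assembly.method or "").upper():
        return False
    if assembly.resolution is None:
        log.info("assembly %s has no resolution record", assembly.assembly_id)
        return False
    if not assembly.resolution < max_resolution:
        return False
    accessions = set()
    for chain in assembly.chains:
        entry = mapping.get(assembly.assembly_id, chain.chain_id)
        if entry is not None:
            accessions.add(entry.accession)
    return len(accessions) >= 2


def min_interchain_distance(chain_a: Chain, chain_b: Chain) -> float:
    """Smallest atom-atom distance between two chains."""
    ca, cb = chain_a.atom_coords(), chain_b.atom_coords()
    if len(ca) == 0 or len(cb) == 0:
        return np.inf
    dist, _ = cKDTree(cb).query(ca, k=1)
    return float(np.min(dist))


def chains_in_contact(
    chain_a: Chain, chain_b: Chain, cutoff: float = DEFAULT_CONTACT_CUTOFF
) -> bool:
    return min_interchain_distance(chain_a, chain_b) < cutoff


def extract_hetero_dimers(
    assembly: Assembly,
    mapping: ProteinMapping,
    contact_cutoff: float = DEFAULT_CONTACT_CUTOFF,
    reference_sequences: dict[str, str] | None = None,
    reference_families: dict[str, str] | None = None,
) -> list[HeteroDimer]:
    """All unordered chain pairs with different accessions and at least one
    inter-chain atom pair below ``contact_cutoff``.

    Chains missing from the mapping table fall back to
    :func:`map_by_identity` against ``reference_sequences`` when given and
    are otherwise skipped with a warning.  The output order is deterministic
    (sorted by chain ids).
    """
    metas: dict[str, MappingEntry] = {}
    for chain in assembly.chains:
        entry = mapping.get(assembly.assembly_id, chain.chain_id)
        if entry is None and reference_sequences:
            acc = map_by_identity(chain, reference_sequences)
            if acc is not None:
                fam = (reference_families or {}).get(acc, acc)
                entry = MappingEntry(acc, fam)
        if entry is None:
            warnings.warn(
                f"chain {assembly.assembly_id}/{chain.chain_id} has no protein "
                f"mapping; skipped"
            )
            continue
        metas[chain.chain_id] = entry
    dimers: list[HeteroDimer] = []
    mapped = sorted(metas, key=str)
    for i, cid_a in enumerate(mapped):
        for cid_b in mapped[i + 1:]:
            ca, cb = assembly.chain(cid_a), assembly.chain(cid_b)
            ma, mb = metas[cid_a], metas[cid_b]
            if ma.accession == mb.accession:
                continue
            if min_interchain_distance(ca, cb) >= contact_cutoff:
                continue
            if not canonical_chain_order(ca, ma, cb, mb):
                ca, cb, ma, mb = cb, ca, mb, ma
            dimers.append(
                HeteroDimer(
                    assembly_id=assembly.assembly_id,
                    chainX=ca, chainY=cb,
                    accX=ma.accession, accY=mb.accession,
                    famX=ma.family, famY=mb.family,
                )
            )
    dimers.sort(key=lambda d: d.sort_key())
    return dimers


def map_by_identity(
    chain: Chain, reference_sequences: dict[str, str]
) -> str | None:
    """Deterministic global-alignment fallback for chains without a mapping
    table entry.

    Returns the accession of the reference with the highest global alignment
    identity, provided at least 90% of the chain aligns to it; ties go to the
    lexicographically smallest accession.  Chains shorter than 30 residues
    are never mapped.
    """
    if len(chain.seqres) < MIN_CHAIN_LENGTH:
        return None
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -1.0
    aligner.extend_gap_score = -0.5
    best: tuple[float, str] | None = None
    for acc in sorted(reference_sequences):
        ref = reference_sequences[acc]
        aln = aligner.align(chain.seqres, ref)[0]
        aligned_cols = 0
        identical = 0
        for (qs, qe), (ts, te) in zip(*aln.aligned):
            aligned_cols += qe - qs
            identical += sum(
                chain.seqres[qs + k] == ref[ts + k] for k in range(qe - qs)
            )
        coverage = aligned_cols / len(chain.seqres)
        if coverage < MIN_IDENTITY_COVERAGE:
            continue
        identity = identical / len(chain.seqres)
        if best is None or identity > best[0]:
            best = (identity, acc)
    return best[1] if best is not None else None


def read_mapping(path: str | Path) -> ProteinMapping:
    """Read the TSV mapping table (assembly_id, chain_id, accession, family)."""
    import pandas as pd

    frame = pd.read_csv(path, sep="\t", dtype=str)
    required = {"assembly_id", "chain_id", "accession", "family"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"mapping table misses columns: {sorted(missing)}")
    mapping = ProteinMapping()
    for row in frame.itertuples(index=False):
        mapping.add(row.assembly_id, row.chain_id, row.accession, row.family)
    return mapping


def write_mapping(mapping: ProteinMapping, path: str | Path) -> None:
    lines = ["assembly_id\tchain_id\taccession\tfamily"]
    for (aid, cid) in sorted(mapping.entries):
        e = mapping.entries[(aid, cid)]
        lines.append(f"{aid}\t{cid}\t{e.accession}\t{e.family}")
    Path(path).write_text("\n".join(lines) + "\n")
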