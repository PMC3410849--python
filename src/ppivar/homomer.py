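"""Homo-oligomer best-match filtering of interface comparisons.

A protein can bind several copies of the same partner when that partner
forms a homo-oligomer, which produces genuinely different interfaces for
one protein pair.  To quantify how much of the observed interface
variability this explains, a comparison X/Y vs X'/Y' is only retained when
it is the best match among all alternative interfaces that X' or Y' forms
with chains of the same homomer, and the same holds with the roles of the
two dimers swapped.

Homomers come in two flavors: *sequence* homomers (interacting chains with
identical SEQRES) and *structural* homomers (interacting chains from the
same family, which look homo-oligomeric despite sequence divergence).
Structural homomers are only meaningful at the Interolog level and only for
interactions between two different families.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import Assembly, Chain, HeteroDimer
from .structures import DEFAULT_CONTACT_CUTOFF, chains_in_contact


@dataclass
class AlternativeSet:
    """The focal dimer plus all homomer-connected alternative interfaces."""

    focal: HeteroDimer
    alternatives: list[HeteroDimer]
    mode: str  # 'sequence' or 'structural'


def find_homomer_partners(
    chain: Chain,
    assembly: Assembly,
    mode: str = "sequence",
    families: dict[str, str] | None = None,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
) -> list[Chain]:
    """Chains of the assembly forming one homomer with the query chain.

    Partners must be sequence-identical (mode='sequence') or come from the
    same family (mode='structural', requires per-chain ``families``), and be
    connected to the query through the contact graph restricted to such
    chains; the closure makes all subunits of an n-ring one homomer even
    when not pairwise in contact.  The query itself is not returned.
    """
    if mode not in ("sequence", "structural"):
        raise ValueError(f"unknown homomer mode {mode!r}")
    if mode == "structural" and families is None:
        raise ValueError("structural mode needs per-chain family labels")

    def same_unit(other: Chain) -> bool:
        if other.chain_id == chain.chain_id:
            return False
        if mode == "sequence":
            return other.seqres == chain.seqres
        return families.get(other.chain_id) == families.get(chain.chain_id)

    candidates = [c for c in assembly.chains if same_unit(c)]
    members = {chain.chain_id}
    frontier = [chain]
    by_id = {c.chain_id: c for c in candidates}
    while frontier:
        current = frontier.pop()
        for cid, cand in list(by_id.items()):
            if chains_in_contact(current, cand, cutoff):
                members.add(cid)
                frontier.append(cand)
                del by_id[cid]
    return [c for c in assembly.chains if c.chain_id in members - {chain.chain_id}]


def collect_alternatives(
    focal: HeteroDimer,
    assembly: Assembly,
    assembly_dimers: list[HeteroDimer],
    mode: str = "sequence",
    families: dict[str, str] | None = None,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
) -> AlternativeSet:
    """All interfaces competing with ``focal`` through a homomer.

    These are the interfaces of chain X' with every homomer partner of Y',
    the interfaces of Y' with every homomer partner of X', and X'/Y' itself,
    restricted to extracted hetero-dimers of the same assembly.
    """
    partners_x = {
        c.chain_id
        for c in find_homomer_partners(focal.chainX, assembly, mode, families, cutoff)
    }
    partners_y = {
        c.chain_id
        for c in find_homomer_partners(focal.chainY, assembly, mode, families, cutoff)
    }
    alternatives = []
    for dimer in assembly_dimers:
        cx, cy = dimer.chainX.chain_id, dimer.chainY.chain_id
        fx, fy = focal.chainX.chain_id, focal.chainY.chain_id
        pair = {cx, cy}
        if pair == {fx, fy}:
            alternatives.append(dimer)  # the focal interface itself
        elif fx in pair and (pair - {fx}) <= partners_y:
            alternatives.append(dimer)
        elif fy in pair and (pair - {fy}) <= partners_x:
            alternatives.append(dimer)
    return AlternativeSet(focal, alternatives, mode)


def best_match_filter(
    focal_similarity: float,
    alternative_similarities: list[float],
    higher_is_better: bool = True,
) -> bool:
    """Retain a comparison iff it is the best match among the alternatives.

    Ties retain: an alternative exactly as good as the focal interface does
    not discard the comparison (the alternative set always contains the
    focal interface itself).
    """
    if not alternative_similarities:
        return True
    if higher_is_better:
        return focal_similarity >= max(alternative_similarities)
    return focal_similarity <= min(alternative_similarities)


def filtered_distributions(
    forest,
    comparer,
    bins,
    mode: str = "sequence",
    caps: tuple[int, int] = (50, 50),
    n_boot: int = 0,
    seed: int = 0,
):
    """Recompute the hierarchy distributions from best-match-retained
    comparisons only.

    mode='sequence' returns {'SameSeq': ..., 'SameProt': ..., 'Interolog':
    ...}; mode='structural' is only defined for the Interolog distribution,
    because at the two lower levels it would compare interfaces of
    different protein pairs.
    """
    from . import distributions as dist

    filtered = comparer.with_homomer_mode(mode)

    def compute(func, **kwargs):
        try:
            return func(forest, filtered, bins, n_boot=n_boot, seed=seed, **kwargs)
        except dist.UndefinedDistributionError:
            return None  # every comparison of the level was skipped/discarded

    if mode == "structural":
        return {"Interolog": compute(dist.d_interolog, caps=caps)}
    return {
        "SameSeq": compute(dist.d_sameseq),
        "SameProt": compute(dist.d_sameprot),
        "Interolog": compute(dist.d_interolog, caps=caps),
    }
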