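"""Three-level redundancy hierarchy over hetero-dimers.

Dimers of the same unordered pair of SEQRES sequences form a SameSeq group;
SameSeq groups with the same unordered accession pair form a SameProt
group; SameProt groups with the same unordered family pair form an
Interolog group.  The hierarchy is a partition at every level, so weighting
each group equally removes the over-representation of well-studied
complexes, proteins and families.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .model import HeteroDimer

LEVELS = ("SameSeq", "SameProt", "Interolog")


@dataclass
class GroupNode:
    level: str
    key: tuple
    children: list["GroupNode"] = field(default_factory=list)
    dimers: list[HeteroDimer] = field(default_factory=list)  # SameSeq only

    def members(self) -> list[HeteroDimer]:
        """All dimers below this node."""
        if self.level == "SameSeq":
            return list(self.dimers)
        return [d for child in self.children for d in child.members()]

    def n_assemblies(self) -> int:
        return len({d.assembly_id for d in self.members()})


def build_hierarchy(dimers: list[HeteroDimer]) -> list[GroupNode]:
    """Partition dimers into the SameSeq / SameProt / Interolog forest.

    Group keys are unordered pairs.  The SameSeq key additionally carries
    the accession pair and the SameProt key the family pair, so that a
    group always has exactly one parent even if an identical sequence pair
    ever occurred under two different protein pairs.  Dimers without a
    family label are placed in a singleton pseudo-family.
    """
    sameseq: dict[tuple, GroupNode] = {}
    for dimer in sorted(dimers, key=lambda d: d.sort_key()):
        fam_pair = dimer.fam_pair
        if not all(fam_pair):
            warnings.warn(
                f"dimer {dimer.uid} lacks a family id; using a singleton "
                f"pseudo-family"
            )
            fam_pair = tuple(
                f or f"_singleton_{a}"
                for f, a in zip((dimer.famX, dimer.famY), (dimer.accX, dimer.accY))
            )
        key = (fam_pair, dimer.prot_pair, dimer.seq_pair)
        node = sameseq.setdefault(key, GroupNode("SameSeq", key))
        node.dimers.append(dimer)

    sameprot: dict[tuple, GroupNode] = {}
    for key in sorted(sameseq):
        fam_pair, prot_pair, _ = key
        parent = sameprot.setdefault(
            (fam_pair, prot_pair), GroupNode("SameProt", (fam_pair, prot_pair))
        )
        parent.children.append(sameseq[key])

    interolog: dict[tuple, GroupNode] = {}
    for key in sorted(sameprot):
        fam_pair, _ = key
        parent = interolog.setdefault(fam_pair, GroupNode("Interolog", fam_pair))
        parent.children.append(sameprot[key])
    return [interolog[k] for k in sorted(interolog)]


def eligible_groups(forest: list[GroupNode], level: str) -> list[GroupNode]:
    """Groups that can contribute comparisons to the given level's
    distribution.

    SameSeq groups need at least two members (from different assemblies or
    as copies within one assembly); SameProt groups need at least two
    SameSeq children; Interolog groups at least two SameProt children.
    """
    if level == "SameSeq":
        return [
            s
            for g in forest
            for p in g.children
            for s in p.children
            if len(s.dimers) >= 2
        ]
    if level == "SameProt":
        return [p for g in forest for p in g.children if len(p.children) >= 2]
    if level == "Interolog":
        return [g for g in forest if len(g.children) >= 2]
    raise ValueError(f"unknown level {level!r}")


def hierarchy_rows(forest: list[GroupNode]) -> list[dict]:
    """Flat dimer -> group-keys table for TSV output."""
    rows = []
    for g in forest:
        for p in g.children:
            for s in p.children:
                for d in s.dimers:
                    rows.append(
                        {
                            "dimer_id": d.uid,
                            "sameseq_key_hash": f"{hash(s.key) & 0xFFFFFFFF:08x}",
                            "sameprot_key": "|".join(p.key[1]),
                            "interolog_key": "|".join(g.key),
                            "copy_number": d.copy_number,
                        }
                    )
    return rows
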