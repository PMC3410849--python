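"""Cached pairwise comparison engine over a set of annotated hetero-dimers.

The engine owns the similarity records (computed lazily, symmetric in the
pair), and optionally applies homomer best-match filtering: a comparison is
used only when it is the best match among all homomer-connected alternative
interfaces on either side.
"""

from __future__ import annotations

from .homomer import best_match_filter, collect_alternatives
from .model import Assembly, HeteroDimer
from .similarity import (
    DEFAULT_MIN_COVERAGE,
    HIGHER_IS_BETTER,
    MEASURES,
    SimilarityRecord,
    similarity_record,
)
from .structures import DEFAULT_CONTACT_CUTOFF


class PairwiseComparer:
    """Compare annotated dimers, with caching and optional homomer filtering.

    Parameters
    ----------
    dimers:
        All annotated dimers of the data set (needed to resolve homomer
        alternatives, not just the two being compared).
    assemblies:
        Source assemblies by id; required for homomer modes.
    measure:
        Which measure :meth:`compare` returns ('fps', 'l_rms' or 'i_rms').
    homomer_mode:
        'off', 'sequence' or 'structural'.
    """

    def __init__(
        self,
        dimers: list[HeteroDimer],
        assemblies: dict[str, Assembly] | None = None,
        measure: str = "fps",
        measures: tuple[str, ...] = MEASURES,
        min_coverage: float = DEFAULT_MIN_COVERAGE,
        homomer_mode: str = "off",
        families: dict[tuple[str, str], str] | None = None,
        contact_cutoff: float = DEFAULT_CONTACT_CUTOFF,
        include_intra_assembly: bool = True,
    ) -> None:
        if measure not in MEASURES:
            raise ValueError(f"unknown measure {measure!r}")
        self.dimers = {d.uid: d for d in dimers}
        self.by_assembly: dict[str, list[HeteroDimer]] = {}
        for d in dimers:
            self.by_assembly.setdefault(d.assembly_id, []).append(d)
        self.assemblies = assemblies or {}
        self.measure = measure
        self.measures = measures
        self.min_coverage = min_coverage
        self.homomer_mode = homomer_mode
        self.families = families or {}
        self.contact_cutoff = contact_cutoff
        self.include_intra_assembly = include_intra_assembly
        self._records: dict[tuple[str, str], SimilarityRecord | None] = {}
        self._alternatives: dict[tuple[str, str], list[HeteroDimer]] = {}
        self.filter_log: list[dict] = []

    # -- plain similarities ------------------------------------------------

    def record(self, a: HeteroDimer, b: HeteroDimer) -> SimilarityRecord | None:
        """Similarity record for an unordered dimer pair (cached)."""
        if a.uid > b.uid:
            a, b = b, a
        key = (a.uid, b.uid)
        if key not in self._records:
            self._records[key] = similarity_record(
                a, b, measures=self.measures, min_coverage=self.min_coverage
            )
        return self._records[key]

    def similarity(self, a: HeteroDimer, b: HeteroDimer) -> float | None:
        rec = self.record(a, b)
        return None if rec is None else rec.value(self.measure)

    # -- homomer filtering -------------------------------------------------

    def with_homomer_mode(self, mode: str) -> "PairwiseComparer":
        """A comparer sharing this one's caches but filtering with ``mode``."""
        clone = object.__new__(PairwiseComparer)
        clone.__dict__ = dict(self.__dict__)
        clone.homomer_mode = mode
        clone.filter_log = []
        return clone

    def _chain_families(self, assembly_id: str) -> dict[str, str]:
        return {
            cid: fam
            for (aid, cid), fam in self.families.items()
            if aid == assembly_id
        }

    def alternatives(self, focal: HeteroDimer, mode: str) -> list[HeteroDimer]:
        key = (focal.uid, mode)
        if key not in self._alternatives:
            assembly = self.assemblies.get(focal.assembly_id)
            if assembly is None:
                raise ValueError(
                    f"assembly {focal.assembly_id} not available for homomer "
                    f"filtering"
                )
            alt = collect_alternatives(
                focal,
                assembly,
                self.by_assembly.get(focal.assembly_id, []),
                mode=mode,
                families=self._chain_families(focal.assembly_id),
                cutoff=self.contact_cutoff,
            )
            self._alternatives[key] = alt.alternatives
        return self._alternatives[key]

    def _best_match(self, a: HeteroDimer, b: HeteroDimer, focal: float) -> bool:
        """Is sim(a, b) the best among a's comparisons to b's alternatives?"""
        alt_sims = []
        for alt in self.alternatives(b, self.homomer_mode):
            sim = self.similarity(a, alt)
            if sim is not None:
                alt_sims.append(sim)
        return best_match_filter(
            focal, alt_sims, higher_is_better=HIGHER_IS_BETTER[self.measure]
        )

    def compare(self, a: HeteroDimer, b: HeteroDimer) -> float | None:
        """Measure value for the pair, after any homomer filtering.

        Returns None when the comparison is undefined, excluded as an
        intra-assembly copy pair, or discarded by the best-match rule.
        """
        if not self.include_intra_assembly and a.assembly_id == b.assembly_id:
            return None
        value = self.similarity(a, b)
        if value is None or self.homomer_mode == "off":
            return value
        if self.homomer_mode == "structural" and a.famX == a.famY:
            # Structural homomers are only defined for interactions between
            # two different families; such comparisons pass unfiltered.
            return value
        retained = self._best_match(a, b, value) and self._best_match(b, a, value)
        self.filter_log.append(
            {
                "dimerA": a.uid,
                "dimerB": b.uid,
                "measure": self.measure,
                "value": value,
                "mode": self.homomer_mode,
                "retained": retained,
            }
        )
        return value if retained else None
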