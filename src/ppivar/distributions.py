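"""Hierarchical, redundancy-corrected interface similarity distributions.

The three distributions answer: if an interaction is observed twice, how
similar are the two interfaces, for

* D-SameSeq   - sequence-identical protein pairs,
* D-SameProt  - the same proteins allowing minor sequence variants,
* D-Interolog - different protein pairs from the same family pair.

Each is built bottom-up over the grouping hierarchy with *unweighted*
averaging at every step, so one heavily deposited complex, protein or
family contributes no more than any other: per-group histograms are
averaged into the parent's distribution, up to the family (Interolog)
level, and finally over families.  Standard errors per bin come from a
bootstrap over the top-level (family) groups.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .grouping import GroupNode

DEFAULT_CAPS = (50, 50)  # max SameProt children per family, SameSeq per protein


@dataclass
class BinSpec:
    """Ordered bin boundaries; ``open_top`` makes the last bin unbounded."""

    edges: tuple[float, ...]
    open_top: bool = False

    def __post_init__(self) -> None:
        self.edges = tuple(float(e) for e in self.edges)
        if any(b <= a for a, b in zip(self.edges, self.edges[1:])):
            raise ValueError("bin edges must be strictly increasing")

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1 + (1 if self.open_top else 0)

    def numpy_edges(self) -> np.ndarray:
        edges = list(self.edges)
        if self.open_top:
            edges.append(np.inf)
        return np.asarray(edges)

    def labels(self) -> list[tuple[float, float]]:
        e = self.numpy_edges()
        return list(zip(e[:-1], e[1:]))


def fps_bins() -> BinSpec:
    """Ten similarity ranges 0.0-0.1 ... 0.9-1.0."""
    return BinSpec(tuple(np.round(np.linspace(0, 1, 11), 1)))


def lrms_bins() -> BinSpec:
    """1-A bins from 0 to 9 A with an open '>9 A' top bin."""
    return BinSpec(tuple(float(i) for i in range(10)), open_top=True)


@dataclass
class Distribution:
    bins: BinSpec
    p: np.ndarray
    se: np.ndarray | None = None
    n_top_groups: int = 0
    n_comparisons: int = 0
    #: per-top-level-group probability vectors; basis of the bootstrap
    group_p: list[np.ndarray] = field(default_factory=list, repr=False)

    def rows(self) -> list[dict]:
        out = []
        for (lo, hi), p, se in zip(
            self.bins.labels(),
            self.p,
            self.se if self.se is not None else [None] * len(self.p),
        ):
            out.append(
                {
                    "bin_low": lo,
                    "bin_high": "inf" if np.isinf(hi) else hi,
                    "p": float(p),
                    "se": None if se is None else float(se),
                }
            )
        return out


class UndefinedDistributionError(ValueError):
    """No eligible group contributed any comparison."""


def histogram(values, bins: BinSpec) -> np.ndarray:
    """Normalized histogram; bins are half-open [a, b), the last closed
    (or unbounded for open-top specs)."""
    values = np.asarray(list(values), dtype=float)
    if values.size == 0:
        raise UndefinedDistributionError("no values to histogram")
    edges = bins.numpy_edges()
    counts, _ = np.histogram(values, edges)
    below = np.sum(values < edges[0])
    if below:
        raise ValueError(f"{below} value(s) below the first bin edge")
    return counts / counts.sum()


def _pair_values(comparer, members_a, members_b=None):
    """Similarities of all pairs within one list, or across two lists."""
    if members_b is None:
        pairs = itertools.combinations(members_a, 2)
    else:
        pairs = itertools.product(members_a, members_b)
    values = []
    for a, b in pairs:
        v = comparer.compare(a, b)
        if v is not None:
            values.append(v)
    return values


def _average(vectors: list[np.ndarray]) -> np.ndarray:
    return np.mean(np.vstack(vectors), axis=0)


def bootstrap_se(
    group_p: list[np.ndarray], n_boot: int = 200, seed: int = 0
) -> np.ndarray:
    """Per-bin standard error from resampling top-level groups."""
    if n_boot < 1:
        raise ValueError("n_boot must be positive")
    if len(group_p) < 2:
        raise UndefinedDistributionError("need >=2 top-level groups for SE")
    rng = np.random.default_rng(seed)
    stack = np.vstack(group_p)
    n = len(group_p)
    means = np.empty((n_boot, stack.shape[1]))
    for i in range(n_boot):
        idx = rng.integers(0, n, size=n)
        means[i] = stack[idx].mean(axis=0)
    return means.std(axis=0, ddof=1)


def _finish(
    bins: BinSpec,
    group_p: list[np.ndarray],
    n_comparisons: int,
    n_boot: int,
    seed: int,
) -> Distribution:
    if not group_p:
        raise UndefinedDistributionError("no eligible group with comparisons")
    p = _average(group_p)
    se = None
    if n_boot and len(group_p) >= 2:
        se = bootstrap_se(group_p, n_boot, seed)
    return Distribution(
        bins=bins,
        p=p,
        se=se,
        n_top_groups=len(group_p),
        n_comparisons=n_comparisons,
        group_p=group_p,
    )


def d_sameseq(
    forest: list[GroupNode],
    comparer,
    bins: BinSpec | None = None,
    n_boot: int = 0,
    seed: int = 0,
) -> Distribution:
    """Similarity distribution for sequence-identical interaction pairs.

    Every SameSeq group with >=2 members yields the histogram of all its
    pairwise member similarities; histograms are averaged into SameProt,
    then Interolog distributions, and finally over families.
    """
    bins = bins or fps_bins()
    group_p, total = [], 0
    for g in forest:
        prot_ps = []
        for p in g.children:
            seq_ps = []
            for s in p.children:
                if len(s.dimers) < 2:
                    continue
                values = _pair_values(comparer, s.dimers)
                if values:
                    seq_ps.append(histogram(values, bins))
                    total += len(values)
            if seq_ps:
                prot_ps.append(_average(seq_ps))
        if prot_ps:
            group_p.append(_average(prot_ps))
    return _finish(bins, group_p, total, n_boot, seed)


def d_sameprot(
    forest: list[GroupNode],
    comparer,
    bins: BinSpec | None = None,
    n_boot: int = 0,
    seed: int = 0,
) -> Distribution:
    """Distribution for the same proteins under minor sequence variation.

    Within a SameProt group, every unordered pair of distinct SameSeq
    children contributes the histogram of all cross-child comparisons
    (within-child pairs are excluded); pair histograms are averaged per
    SameProt group, then up the hierarchy as for D-SameSeq.
    """
    bins = bins or fps_bins()
    group_p, total = [], 0
    for g in forest:
        prot_ps = []
        for p in g.children:
            if len(p.children) < 2:
                continue
            pair_ps = []
            for s1, s2 in itertools.combinations(p.children, 2):
                values = _pair_values(comparer, s1.dimers, s2.dimers)
                if values:
                    pair_ps.append(histogram(values, bins))
                    total += len(values)
            if pair_ps:
                prot_ps.append(_average(pair_ps))
        if prot_ps:
            group_p.append(_average(prot_ps))
    return _finish(bins, group_p, total, n_boot, seed)


def d_interolog(
    forest: list[GroupNode],
    comparer,
    bins: BinSpec | None = None,
    caps: tuple[int, int] | None = DEFAULT_CAPS,
    n_boot: int = 0,
    seed: int = 0,
) -> Distribution:
    """Distribution for different protein pairs of the same family pair.

    For every unordered pair of distinct SameProt children of a family
    group, each (SameSeq from one, SameSeq from the other) combination
    contributes the histogram of its cross comparisons; these are averaged
    to the protein-pair distribution, over protein pairs to the family
    distribution, and over families to D-Interolog.  When a family has more
    than ``caps[0]`` protein pairs, or a protein more than ``caps[1]``
    sequence pairs, a seeded subsample is used.
    """
    bins = bins or fps_bins()
    rng = np.random.default_rng(seed)
    max_prots, max_seqs = caps if caps is not None else (None, None)

    def subsample(items: list, cap: int | None) -> list:
        if cap is None or len(items) <= cap:
            return items
        idx = sorted(rng.choice(len(items), size=cap, replace=False))
        return [items[i] for i in idx]

    group_p, total = [], 0
    for g in forest:
        if len(g.children) < 2:
            continue
        prots = subsample(g.children, max_prots)
        pair_ps = []
        for p1, p2 in itertools.combinations(prots, 2):
            seqs1 = subsample(p1.children, max_seqs)
            seqs2 = subsample(p2.children, max_seqs)
            seq_ps = []
            for s1 in seqs1:
                for s2 in seqs2:
                    values = _pair_values(comparer, s1.dimers, s2.dimers)
                    if values:
                        seq_ps.append(histogram(values, bins))
                        total += len(values)
            if seq_ps:
                pair_ps.append(_average(seq_ps))
        if pair_ps:
            group_p.append(_average(pair_ps))
    return _finish(bins, group_p, total, n_boot, seed)


def plot_distributions(
    by_level: dict[str, "Distribution | None"],
    title: str = "Interface similarity",
    ax=None,
):
    """Grouped-bar plot of the three hierarchy distributions (convenience;
    requires matplotlib)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    levels = [lv for lv, d in by_level.items() if d is not None]
    if not levels:
        raise ValueError("no distribution to plot")
    n_levels = len(levels)
    width = 0.8 / n_levels
    shades = ["0.1", "0.45", "0.75"]
    for i, level in enumerate(levels):
        d = by_level[level]
        x = np.arange(d.bins.n_bins) + (i - (n_levels - 1) / 2) * width
        ax.bar(
            x, d.p, width=width, label=f"D-{level}",
            yerr=d.se, color=shades[i % len(shades)], capsize=2,
        )
    d0 = by_level[levels[0]]
    labels = [
        f"{lo:g}-{'inf' if np.isinf(hi) else f'{hi:g}'}"
        for lo, hi in d0.bins.labels()
    ]
    ax.set_xticks(np.arange(d0.bins.n_bins))
    ax.set_xticklabels(labels, rotation=45, ha="right")
    ax.set_ylabel("probability")
    ax.set_title(title)
    ax.legend()
    return ax


def cumulative(
    distribution: Distribution, threshold: float, side: str = "below"
) -> float:
    """Probability mass in bins entirely below (or above) ``threshold``.

    The threshold must coincide with a bin edge; there is no interpolation.
    """
    edges = distribution.bins.numpy_edges()
    matches = np.nonzero(np.isclose(edges, threshold))[0]
    if len(matches) == 0:
        raise ValueError(f"threshold {threshold} is not a bin edge")
    k = int(matches[0])
    if side == "below":
        return float(np.sum(distribution.p[:k]))
    if side == "above":
        return float(np.sum(distribution.p[k:]))
    raise ValueError(f"side must be 'below' or 'above', got {side!r}")
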