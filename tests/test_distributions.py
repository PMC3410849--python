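"""Histogram conventions, hierarchical averaging semantics, caps, bootstrap."""

import itertools

import numpy as np
import pytest

from ppivar.distributions import (
    BinSpec,
    UndefinedDistributionError,
    bootstrap_se,
    cumulative,
    d_interolog,
    d_sameprot,
    d_sameseq,
    fps_bins,
    histogram,
    lrms_bins,
)
from ppivar.grouping import build_hierarchy

from test_grouping import stub_dimer


class StubComparer:
    """Dict-backed comparer: similarity looked up by unordered uid pair."""

    def __init__(self, table):
        self.table = {frozenset(k): v for k, v in table.items()}
        self.queried = []

    def compare(self, a, b):
        self.queried.append(frozenset((a.uid, b.uid)))
        return self.table.get(frozenset((a.uid, b.uid)))


def seq(i):
    return f"AAAA{chr(65 + i)}"


def make_dimers(n, seq_pair=(0, 10), prot=("P1", "P2"), fam=("F1", "F2"), tag=""):
    return [
        stub_dimer(f"{tag}x{i}", (seq(seq_pair[0]), seq(seq_pair[1])), prot, fam)
        for i in range(n)
    ]


class TestHistogram:
    def test_top_edge_closed(self):
        p = histogram([1.0, 1.0, 1.0], fps_bins())
        assert p[-1] == 1.0 and p.sum() == 1.0

    def test_half_open_bins(self):
        p = histogram([0.05, 0.95], fps_bins())
        assert p[0] == 0.5 and p[-1] == 0.5

    def test_open_top_bin_collects_large_values(self):
        p = histogram([0.5, 25.0, 100.0], lrms_bins())
        assert p[0] == pytest.approx(1 / 3)
        assert p[-1] == pytest.approx(2 / 3)

    def test_uniform_draws_fill_bins_evenly(self):
        rng = np.random.default_rng(17)
        p = histogram(rng.uniform(0, 1, size=1000), fps_bins())
        assert np.all(np.abs(p - 0.1) < 0.03)

    def test_empty_values_undefined(self):
        with pytest.raises(UndefinedDistributionError):
            histogram([], fps_bins())

    def test_edges_must_increase(self):
        with pytest.raises(ValueError):
            BinSpec((0.0, 0.5, 0.5, 1.0))


def pair_table(dimers_by_group, value_fn):
    table = {}
    for members in dimers_by_group:
        for a, b in itertools.combinations(members, 2):
            table[(a.uid, b.uid)] = value_fn(a, b)
    return table


class TestDSameSeq:
    def test_single_group_equals_own_histogram(self):
        dimers = make_dimers(3)
        values = {("x0", "x1"): 1.0, ("x0", "x2"): 0.05, ("x1", "x2"): 0.05}
        comparer = StubComparer(
            {(f"{a}:A-B", f"{b}:A-B"): v for (a, b), v in values.items()}
        )
        forest = build_hierarchy(dimers)
        d = d_sameseq(forest, comparer, fps_bins())
        assert d.p[0] == pytest.approx(2 / 3)
        assert d.p[-1] == pytest.approx(1 / 3)
        assert d.n_top_groups == 1

    def test_groups_weighted_equally_regardless_of_size(self):
        """One family with 100 comparisons all conserved, another with one
        divergent comparison: each contributes half."""
        big = make_dimers(15, fam=("F1", "G1"), tag="big")
        small = make_dimers(2, fam=("F2", "G2"), tag="sml")
        table = {}
        for a, b in itertools.combinations(big, 2):  # 105 comparisons
            table[(a.uid, b.uid)] = 1.0
        table[(small[0].uid, small[1].uid)] = 0.05
        d = d_sameseq(build_hierarchy(big + small), StubComparer(table), fps_bins())
        assert d.n_top_groups == 2
        assert d.p[-1] == pytest.approx(0.5)
        assert d.p[0] == pytest.approx(0.5)

    def test_probabilities_sum_to_one(self):
        big = make_dimers(4)
        table = {
            (a.uid, b.uid): 0.5 for a, b in itertools.combinations(big, 2)
        }
        d = d_sameseq(build_hierarchy(big), StubComparer(table), fps_bins())
        assert d.p.sum() == pytest.approx(1.0, abs=1e-9)

    def test_no_eligible_group_raises(self):
        d1 = make_dimers(1)
        with pytest.raises(UndefinedDistributionError):
            d_sameseq(build_hierarchy(d1), StubComparer({}), fps_bins())


class TestDSameProt:
    def build(self):
        wild = make_dimers(2, seq_pair=(0, 10), tag="wt")
        mutant = make_dimers(2, seq_pair=(1, 10), tag="mt")
        return wild, mutant

    def test_only_cross_child_comparisons_used(self):
        wild, mutant = self.build()
        table = {}
        for a in wild:
            for b in mutant:
                table[(a.uid, b.uid)] = 1.0
        # poison within-child pairs: would land in bin 0 if ever used
        table[(wild[0].uid, wild[1].uid)] = 0.0
        table[(mutant[0].uid, mutant[1].uid)] = 0.0
        comparer = StubComparer(table)
        d = d_sameprot(build_hierarchy(wild + mutant), comparer, fps_bins())
        assert d.p[-1] == 1.0
        for queried in comparer.queried:
            assert queried != frozenset((wild[0].uid, wild[1].uid))

    def test_three_children_equal_brute_force(self):
        """Three sequence variants: the distribution equals the mean of the
        three pairwise cross histograms, enumerated by hand."""
        children = [
            make_dimers(2, seq_pair=(i, 10), tag=f"v{i}") for i in range(3)
        ]
        rng = np.random.default_rng(3)
        table = {}
        for g1, g2 in itertools.combinations(children, 2):
            for a in g1:
                for b in g2:
                    table[(a.uid, b.uid)] = float(rng.uniform())
        comparer = StubComparer(table)
        flat = [d for c in children for d in c]
        d = d_sameprot(build_hierarchy(flat), comparer, fps_bins())
        hists = []
        for g1, g2 in itertools.combinations(children, 2):
            values = [
                table[(a.uid, b.uid)] for a in g1 for b in g2
            ]
            hists.append(histogram(values, fps_bins()))
        np.testing.assert_allclose(d.p, np.mean(hists, axis=0), atol=1e-12)


class TestDInterolog:
    def build_group(self, n_prots=3, n_seqs=2, n_members=2, seed=4):
        rng = np.random.default_rng(seed)
        prots, table = [], {}
        for p in range(n_prots):
            children = [
                make_dimers(
                    n_members,
                    seq_pair=(2 * s, 11 + p),
                    prot=(f"PA{p}", "PB"),
                    tag=f"p{p}s{s}",
                )
                for s in range(n_seqs)
            ]
            prots.append(children)
        flat = [d for p in prots for c in p for d in c]
        for a, b in itertools.combinations(flat, 2):
            table[(a.uid, b.uid)] = float(rng.uniform())
        return prots, flat, table

    def test_degenerate_group_equals_direct_histogram(self):
        prots, flat, table = self.build_group(n_prots=2, n_seqs=1)
        comparer = StubComparer(table)
        d = d_interolog(build_hierarchy(flat), comparer, fps_bins())
        values = [
            table[(a.uid, b.uid)]
            for a in prots[0][0]
            for b in prots[1][0]
        ]
        np.testing.assert_allclose(d.p, histogram(values, fps_bins()), atol=1e-12)

    def test_caps_not_binding_identical(self):
        prots, flat, table = self.build_group(n_prots=4, n_seqs=3)
        forest = build_hierarchy(flat)
        with_caps = d_interolog(
            build_hierarchy(flat), StubComparer(table), fps_bins(), caps=(50, 50)
        )
        without = d_interolog(
            build_hierarchy(flat), StubComparer(table), fps_bins(), caps=None
        )
        np.testing.assert_allclose(with_caps.p, without.p, atol=1e-12)

    def test_matches_exhaustive_enumeration(self):
        """Uncapped hierarchy equals a from-scratch nested-average oracle."""
        prots, flat, table = self.build_group(n_prots=3, n_seqs=2, n_members=2)
        d = d_interolog(
            build_hierarchy(flat), StubComparer(table), fps_bins(), caps=None
        )
        pair_dists = []
        for p1, p2 in itertools.combinations(prots, 2):
            seq_hists = []
            for c1 in p1:
                for c2 in p2:
                    values = [table[(a.uid, b.uid)] for a in c1 for b in c2]
                    seq_hists.append(histogram(values, fps_bins()))
            pair_dists.append(np.mean(seq_hists, axis=0))
        np.testing.assert_allclose(d.p, np.mean(pair_dists, axis=0), atol=1e-12)

    def test_binding_caps_subsample_deterministically(self):
        prots, flat, table = self.build_group(n_prots=4, n_seqs=3)
        kw = dict(bins=fps_bins(), caps=(2, 2))
        d1 = d_interolog(build_hierarchy(flat), StubComparer(table), seed=9, **kw)
        d2 = d_interolog(build_hierarchy(flat), StubComparer(table), seed=9, **kw)
        np.testing.assert_allclose(d1.p, d2.p, atol=0)


class TestRedundancyInvariance:
    def test_duplicating_a_family_group_changes_nothing(self):
        """The central statistical device: a verbatim duplicate of an entire
        family group leaves all three distributions unchanged."""
        wild = make_dimers(2, seq_pair=(0, 10), tag="wt")
        mutant = make_dimers(2, seq_pair=(1, 10), tag="mt")
        other = make_dimers(3, fam=("F9", "G9"), prot=("P8", "P9"), tag="oth")
        base = wild + mutant + other
        clone = [
            stub_dimer(
                d.assembly_id + "dup",
                (d.chainX.seqres, d.chainY.seqres),
                ("C" + d.accX, "C" + d.accY),
                ("C" + d.famX, "C" + d.famY),
            )
            for d in base
        ]
        rng = np.random.default_rng(6)
        table = {}
        for a, b in itertools.combinations(base, 2):
            v = float(rng.uniform())
            table[(a.uid, b.uid)] = v
            table[(a.uid.replace(":", "dup:"), b.uid.replace(":", "dup:"))] = v
        d_base = d_sameseq(build_hierarchy(base), StubComparer(table), fps_bins())
        d_both = d_sameseq(
            build_hierarchy(base + clone), StubComparer(table), fps_bins()
        )
        np.testing.assert_allclose(d_base.p, d_both.p, atol=1e-12)
        p_base = d_sameprot(build_hierarchy(base), StubComparer(table), fps_bins())
        p_both = d_sameprot(
            build_hierarchy(base + clone), StubComparer(table), fps_bins()
        )
        np.testing.assert_allclose(p_base.p, p_both.p, atol=1e-12)

    def test_inflating_one_group_leaves_other_groups_weight(self):
        """1,000 extra conserved comparisons in one family do not dilute the
        other family's 50% share."""
        flood = make_dimers(46, fam=("F1", "G1"), tag="fl")  # 1035 pairs
        lone = make_dimers(2, fam=("F2", "G2"), tag="ln")
        table = {
            (a.uid, b.uid): 1.0 for a, b in itertools.combinations(flood, 2)
        }
        table[(lone[0].uid, lone[1].uid)] = 0.05
        d = d_sameseq(build_hierarchy(flood + lone), StubComparer(table), fps_bins())
        assert d.p[0] == pytest.approx(0.5)
        assert d.p[-1] == pytest.approx(0.5)


class TestBootstrapSE:
    def test_identical_groups_zero_se(self):
        p = np.array([0.2, 0.8])
        se = bootstrap_se([p, p, p], n_boot=100, seed=1)
        np.testing.assert_allclose(se, 0.0, atol=1e-12)

    def test_two_group_closed_form(self):
        """For two groups the bootstrap mean is p1, (p1+p2)/2 or p2 with
        probabilities 1/4, 1/2, 1/4, so SE per bin tends to |p1-p2|/(2*sqrt(2))."""
        p1 = np.array([1.0, 0.0])
        p2 = np.array([0.0, 1.0])
        se = bootstrap_se([p1, p2], n_boot=4000, seed=2)
        expected = np.abs(p1 - p2) / (2 * np.sqrt(2))
        np.testing.assert_allclose(se, expected, rtol=0.1)

    def test_stability_under_more_resamples(self):
        rng = np.random.default_rng(8)
        groups = [rng.dirichlet(np.ones(5)) for _ in range(6)]
        se1 = bootstrap_se(groups, n_boot=400, seed=3)
        se2 = bootstrap_se(groups, n_boot=800, seed=3)
        np.testing.assert_allclose(se1, se2, rtol=0.1, atol=5e-3)

    def test_single_group_undefined(self):
        with pytest.raises(UndefinedDistributionError):
            bootstrap_se([np.array([1.0])], n_boot=100)


class TestCumulative:
    def from_p(self, p, bins=None):
        from ppivar.distributions import Distribution

        return Distribution(bins or fps_bins(), np.asarray(p))

    def test_mass_below_threshold(self):
        p = np.full(10, 0.1)
        assert cumulative(self.from_p(p), 0.5) == pytest.approx(0.5)

    def test_mass_above_for_distance_measures(self):
        p = np.zeros(10)
        p[0], p[-1] = 0.7, 0.3
        d = self.from_p(p, lrms_bins())
        assert cumulative(d, 2.0, side="above") == pytest.approx(0.3)
        assert cumulative(d, 1.0, side="below") == pytest.approx(0.7)

    def test_non_edge_threshold_rejected(self):
        with pytest.raises(ValueError):
            cumulative(self.from_p(np.full(10, 0.1)), 0.55)

    def test_matches_direct_count(self):
        rng = np.random.default_rng(9)
        values = rng.uniform(0, 1, 500)
        p = histogram(values, fps_bins())
        d = self.from_p(p)
        assert cumulative(d, 0.3) == pytest.approx(np.mean(values < 0.3))
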