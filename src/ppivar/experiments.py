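"""Self-contained benchmark experiments on synthetic worlds.

These drive the whole analysis stack (generation -> extraction ->
annotation -> grouping -> comparison -> distributions) in memory and
return the quantities the package's validation rests on: recovery of the
planted mode-mixture, the direction of the homomer filter's effect, and
the copy-number effect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import distributions as dist
from .annotation import AnnotationConfig, annotate_interface, assign_copy_numbers, passes_size_filter
from .engine import PairwiseComparer
from .grouping import build_hierarchy
from .homomer import filtered_distributions
from .model import HeteroDimer
from .structures import extract_hetero_dimers
from .synthetic import World, WorldSpec, generate_world


def analyze_world(
    world: World,
    measure: str = "fps",
    use_dasa: bool = True,
    homomer_mode: str = "off",
) -> tuple[list, PairwiseComparer]:
    """Extract, annotate and group a world; return (forest, comparer)."""
    config = AnnotationConfig(use_dasa=use_dasa)
    dimers: list[HeteroDimer] = []
    for assembly in world.assemblies:
        extracted = extract_hetero_dimers(assembly, world.mapping)
        surviving = []
        for dimer in extracted:
            dimer.interface = annotate_interface(dimer, config)
            if passes_size_filter(dimer.interface):
                surviving.append(dimer)
        assign_copy_numbers(surviving)
        dimers.extend(surviving)
    forest = build_hierarchy(dimers)
    families = {key: e.family for key, e in world.mapping.entries.items()}
    comparer = PairwiseComparer(
        dimers,
        assemblies={a.assembly_id: a for a in world.assemblies},
        measure=measure,
        measures=(measure,),
        families=families,
        homomer_mode=homomer_mode,
    )
    return forest, comparer


def sameseq_group_low_masses(
    forest, comparer, threshold: float = 0.5
) -> list[float]:
    """Per-family D-SameSeq mass below the threshold (the per-group values
    whose unweighted mean is the reported D-SameSeq mass)."""
    bins = dist.fps_bins()
    d = dist.d_sameseq(forest, comparer, bins)
    k = int(np.nonzero(np.isclose(bins.numpy_edges(), threshold))[0][0])
    return [float(np.sum(p[:k])) for p in d.group_p]


def bootstrap_interval(
    values: list[float], n_boot: int = 2000, seed: int = 0, level: float = 0.99
) -> tuple[float, float, float]:
    """Percentile bootstrap CI for the mean of per-group values."""
    rng = np.random.default_rng(seed)
    values = np.asarray(values)
    means = np.array(
        [
            values[rng.integers(0, len(values), len(values))].mean()
            for _ in range(n_boot)
        ]
    )
    alpha = (1.0 - level) / 2.0
    return (
        float(values.mean()),
        float(np.quantile(means, alpha)),
        float(np.quantile(means, 1.0 - alpha)),
    )


@dataclass
class RecoveryResult:
    mass: float
    ci_low: float
    ci_high: float
    expected: float

    @property
    def covered(self) -> bool:
        return self.ci_low - 1e-12 <= self.expected <= self.ci_high + 1e-12


def recovery_spec(seed: int, mixture=(0.8, 0.2)) -> WorldSpec:
    """Study conditions for mixture recovery: single-copy assemblies of one
    sequence pair per family, two planted modes."""
    return WorldSpec(
        n_families=12,
        prots_per_family=1,
        seqs_per_prot=1,
        obs_per_seq=4,
        modes_per_pair=len(mixture),
        mode_mixture=mixture,
        copy_number_dist={1: 1.0},
        homomer_rate=0.0,
        include_ring=False,
        seed=seed,
    )


def mode_recovery_experiment(
    n_worlds: int = 40,
    base_seed: int = 0,
    mixture=(0.8, 0.2),
    use_dasa: bool = True,
) -> list[RecoveryResult]:
    """Does D-SameSeq recover the planted cross-mode fraction?

    For each replicate world, the D-SameSeq mass below fps 0.5 is compared
    with the closed-form expectation 1 - sum(q_i^2) via a 99% bootstrap CI
    over the per-family distributions.
    """
    results = []
    for i in range(n_worlds):
        seed = base_seed * 100003 + i
        world = generate_world(recovery_spec(seed, mixture))
        forest, comparer = analyze_world(world, use_dasa=use_dasa)
        masses = sameseq_group_low_masses(forest, comparer)
        mass, lo, hi = bootstrap_interval(masses, seed=seed)
        results.append(
            RecoveryResult(mass, lo, hi, world.expected["cross_mode_fraction"])
        )
    return results


def homomer_direction_experiment(
    seeds=(1, 2, 3), use_dasa: bool = False
) -> list[dict]:
    """Effect of sequence-homomer best-match filtering on each level.

    Returns one row per (seed, level) with the top-bin mass and the mass
    below fps 0.5, before and after filtering.
    """
    rows = []
    for seed in seeds:
        spec = WorldSpec(
            n_families=3,
            prots_per_family=2,
            seqs_per_prot=2,
            obs_per_seq=2,
            homomer_rate=0.5,
            copy_number_dist={1: 0.6, 2: 0.4},
            include_ring=False,
            seed=seed,
        )
        world = generate_world(spec)
        forest, comparer = analyze_world(world, use_dasa=use_dasa)
        bins = dist.fps_bins()
        plain = {
            "SameSeq": dist.d_sameseq(forest, comparer, bins),
            "SameProt": dist.d_sameprot(forest, comparer, bins),
            "Interolog": dist.d_interolog(forest, comparer, bins),
        }
        filtered = filtered_distributions(forest, comparer, bins, mode="sequence")
        for level, before in plain.items():
            after = filtered[level]
            if before is None or after is None:
                continue
            rows.append(
                {
                    "seed": seed,
                    "level": level,
                    "top_before": float(before.p[-1]),
                    "top_after": float(after.p[-1]),
                    "low_before": dist.cumulative(before, 0.5),
                    "low_after": dist.cumulative(after, 0.5),
                }
            )
    return rows


def copy_number_experiment(
    seed: int = 0, use_dasa: bool = False, thetas=(0.0, 0.5, 1.0)
) -> list[dict]:
    """Realized D-SameSeq low-similarity mass as the copy-number mean rises
    from 1 (theta=0) to 2 (theta=1)."""
    rows = []
    for i, theta in enumerate(thetas):
        if theta <= 0:
            dist_k = {1: 1.0}
        elif theta >= 1:
            dist_k = {2: 1.0}
        else:
            dist_k = {1: 1.0 - theta, 2: theta}
        spec = WorldSpec(
            n_families=12,
            prots_per_family=1,
            seqs_per_prot=1,
            obs_per_seq=4,
            copy_number_dist=dist_k,
            homomer_rate=0.0,
            include_ring=False,
            seed=seed * 499 + i,
        )
        world = generate_world(spec)
        forest, comparer = analyze_world(world, use_dasa=use_dasa)
        d = dist.d_sameseq(forest, comparer, dist.fps_bins())
        rows.append(
            {
                "theta": theta,
                "low_mass": dist.cumulative(d, 0.5),
                "expected": world.expected["cross_mode_fraction"],
            }
        )
    return rows
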