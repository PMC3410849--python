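"""Shared fixtures: small synthetic chains, docked dimers and worlds.

Everything is generated programmatically; the slow pieces (full worlds) are
session-scoped so the suite builds them once.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings as hypothesis_settings

hypothesis_settings.register_profile("deterministic", derandomize=True)
hypothesis_settings.load_profile("deterministic")

from ppivar.annotation import AnnotationConfig, annotate_interface
from ppivar.model import HeteroDimer
from ppivar.synthetic import (
    WorldSpec,
    binding_modes,
    build_chain,
    dock,
    generate_world,
    transform_chain,
)

# distance-only annotation: fast, sufficient for most geometry tests
FAST = AnnotationConfig(use_dasa=False)


@pytest.fixture(scope="session")
def rod_chains():
    return build_chain(60, fold_seed=1), build_chain(60, fold_seed=2)


@pytest.fixture(scope="session")
def two_modes():
    return binding_modes(60, 2)


def make_dimer(
    chain_x,
    chain_y,
    mode,
    assembly_id="asm",
    accs=("P1", "P2"),
    fams=("F1", "F2"),
    config=FAST,
    rigid=None,
):
    """Dock, optionally move rigidly, and annotate a hetero-dimer."""
    placed_x, placed_y = dock(chain_x, chain_y, mode)
    if rigid is not None:
        rot, shift = rigid
        placed_x = transform_chain(placed_x, rot, shift)
        placed_y = transform_chain(placed_y, rot, shift)
    dimer = HeteroDimer(
        assembly_id, placed_x, placed_y, accs[0], accs[1], fams[0], fams[1]
    )
    dimer.interface = annotate_interface(dimer, config)
    return dimer


@pytest.fixture(scope="session")
def mode_dimers(rod_chains, two_modes):
    """Annotated dimers: two observations of mode 0 and one of mode 1."""
    cx, cy = rod_chains
    return {
        "m0": make_dimer(cx, cy, two_modes[0], assembly_id="a0"),
        "m0_bis": make_dimer(cx, cy, two_modes[0], assembly_id="a1"),
        "m1": make_dimer(cx, cy, two_modes[1], assembly_id="a2"),
    }


@pytest.fixture(scope="session")
def small_world(tmp_path_factory):
    """A small default-parameter world, generated once, with files on disk."""
    out = tmp_path_factory.mktemp("world")
    spec = WorldSpec(
        n_families=2, prots_per_family=2, seqs_per_prot=2, obs_per_seq=2, seed=7
    )
    world = generate_world(spec, out)
    return world, out


@pytest.fixture(scope="session")
def homomer_free_world():
    """A world without homo-oligomeric context (filter no-op reference)."""
    spec = WorldSpec(
        n_families=2,
        prots_per_family=1,
        seqs_per_prot=1,
        obs_per_seq=3,
        copy_number_dist={1: 1.0},
        homomer_rate=0.0,
        include_ring=False,
        seed=11,
    )
    return generate_world(spec)


def random_rigid(seed):
    rng = np.random.default_rng(seed)
    from scipy.spatial.transform import Rotation

    rot = Rotation.random(rng=rng).as_matrix()
    shift = rng.normal(scale=20.0, size=3)
    return rot, shift
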