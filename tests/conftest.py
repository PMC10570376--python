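"""Shared fixtures: random oracle trees and a small synthetic world."""

from __future__ import annotations

import random

import numpy as np
import pytest

import phylonat as pn


def random_bd_newick(n_tips: int, seed: int, death_rate: float = 0.3) -> str:
    """A random birth–death tree (dendropy's simulator: independent of
    the package's own Yule generator, so it can serve as an oracle
    substrate)."""
    from dendropy.simulate import treesim

    tree = treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=death_rate,
        num_extant_tips=n_tips,
        rng=random.Random(seed),
    )
    return tree.as_string(schema="newick", suppress_rooting=True)


def brute_force_mpd(tree: pn.PhyloTree, aliens, natives) -> float:
    """Independent MPD oracle via the full patristic matrix."""
    labels, mat = pn.patristic_matrix(tree)
    idx = {name: i for i, name in enumerate(labels)}
    vals = [mat[idx[a], idx[b]] for a in aliens for b in natives]
    return float(np.mean(vals))


def brute_force_mntd(tree: pn.PhyloTree, aliens, natives) -> float:
    labels, mat = pn.patristic_matrix(tree)
    idx = {name: i for i, name in enumerate(labels)}
    return float(
        np.mean(
            [min(mat[idx[a], idx[b]] for b in natives) for a in aliens]
        )
    )


def random_disjoint_sets(tip_names, rng, max_each: int = 15):
    tips = sorted(tip_names)
    rng.shuffle(tips)
    na = rng.randint(1, min(max_each, len(tips) - 1))
    nb = rng.randint(1, min(max_each, len(tips) - na))
    return set(tips[:na]), set(tips[na: na + nb])


def scale_edges(tree: pn.PhyloTree, c: float) -> pn.PhyloTree:
    out = tree.copy()
    d = out.dendropy_tree
    for node in d.preorder_node_iter():
        if node.edge.length is not None:
            node.edge.length *= c
    return pn.PhyloTree(d)


def small_params(**overrides) -> pn.WorldParams:
    """Scaled-down world for fast replicated experiments."""
    base = dict(
        n_species=150, n_genera=30, n_families=10,
        n_regions=40, cells_per_region=6, richness_per_region=40,
        seed=0,
    )
    base.update(overrides)
    return pn.WorldParams(**base)


def replication_params(**overrides) -> pn.WorldParams:
    """World size used for the replicated recovery / calibration
    experiments: large enough for near-normal ΔMPD sampling, small
    enough to repeat hundreds of times."""
    base = dict(
        n_species=250, n_genera=40, n_families=12,
        n_regions=50, cells_per_region=8, richness_per_region=60,
        seed=0,
    )
    base.update(overrides)
    return pn.WorldParams(**base)


def null_world_params(**overrides) -> pn.WorldParams:
    """A world with no latitude-linked distance effect: flat filtering,
    zero cloglog slopes/interaction, no alien climate filter, no random
    effects."""
    base = dict(
        filtering_latitude_coefficient=0.0,
        beta_mpd=0.0, beta_lat=0.0, beta_int=0.0,
        alien_filter_sd=float("inf"),
        sd_species=0.0, sd_region=0.0,
    )
    base.update(overrides)
    return replication_params(**base)


def delta_mpd_latitude_fit(world, n_reps=200, seed=0):
    """ΔMPD ~ |latitude| weighted fit under the global naturalized
    pool, the package's headline regression."""
    rows = []
    for r in world.regions:
        rows += pn.run_region_pools(
            world.tree, r, [pn.PoolType.GLOBAL_NAT], world.registry,
            continent_regions=world.continent_regions,
            n_reps=n_reps, seed=seed,
        )
    df = pn.results_to_frame(rows)
    lat = {x.region_id: abs(x.latitude) for x in world.regions}
    return pn.fit_weighted_linear(
        df["delta_mpd"],
        {"alat": np.array([lat[i] for i in df["region_id"]])},
        weights=df["weight"],
    )


@pytest.fixture(scope="session")
def small_world() -> pn.SyntheticWorld:
    return pn.generate_world(small_params(seed=42))


@pytest.fixture(scope="session")
def default_world() -> pn.SyntheticWorld:
    """One world at the generator's default study conditions."""
    return pn.generate_world(pn.WorldParams(seed=7))
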