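"""Randomization engine for regional null expectations of cross-group MPD.

For each region the native assemblage and the *number* of naturalized
aliens are held fixed while alien identities are re-drawn uniformly,
without replacement, from a candidate source pool.  Summaries follow the
standard community-phylogenetics conventions:

    ΔMPD    = observed MPD − mean(null MPDs)
    SES.MPD = ΔMPD / sd(null MPDs)          (sample SD, n−1)
    weight  = 1 / var(null MPDs)            (inverse-variance weight)

Positive ΔMPD: aliens more distantly related to natives than chance
(Darwin's naturalization hypothesis); negative: more closely related
(preadaptation).  Because cross-group MPD is linear in the alien set, each
replicate costs O(draw size) once per-species distance sums to the native
set are in hand (see :func:`phylonat.tree.native_distance_sums`).
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pools import PoolType, RegionRecord, SpeciesRegistry, build_pool
from .tree import PhyloTree, crossgroup_mpd, native_distance_sums

__all__ = [
    "NullResult",
    "null_distribution",
    "summarize_null",
    "run_region_pools",
    "results_to_frame",
    "substream",
]

log = logging.getLogger(__name__)


def substream(master_seed: int, *tokens) -> np.random.Generator:
    """Deterministic, order-independent random substream.

    Hashes ``(master_seed, tokens)`` with SHA-256 into entropy for a
    :class:`numpy.random.SeedSequence`, so every (region, pool) pair gets
    its own reproducible stream regardless of processing order.
    """
    digest = hashlib.sha256(
        repr((int(master_seed),) + tuple(tokens)).encode()
    ).digest()
    words = [
        int.from_bytes(digest[i: i + 4], "little") for i in range(0, 16, 4)
    ]
    return np.random.default_rng(
        np.random.SeedSequence([int(master_seed)] + words)
    )


@dataclass
class NullResult:
    """Observed vs null MPD for one region × pool.

    ``ses_mpd`` and ``weight`` are NaN when the null distribution is
    degenerate (zero SD), the 'undefined' flag of the contract.
    """

    region_id: str
    pool: PoolType
    n_native: int
    n_alien: int
    observed_mpd: float
    null_mean: float
    null_sd: float
    delta_mpd: float
    ses_mpd: float
    weight: float
    n_reps: int


def _draw_null_means(
    values: np.ndarray, n_aliens: int, n_reps: int, rng: np.random.Generator
) -> np.ndarray:
    """Means of `n_aliens`-subsets of `values`, drawn without replacement."""
    n = values.size
    keys = rng.random((n_reps, n))
    idx = np.argpartition(keys, n_aliens - 1, axis=1)[:, :n_aliens]
    return values[idx].mean(axis=1)


def null_distribution(
    tree: PhyloTree,
    natives,
    n_aliens: int,
    pool,
    n_reps: int,
    seed,
) -> np.ndarray:
    """Null MPD values from uniform draws of alien sets out of a pool.

    ``seed`` may be an integer or a :class:`numpy.random.Generator`.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if n_aliens < 1:
        raise ValueError("n_aliens must be >= 1")
    natives = set(natives)
    candidates = sorted(set(pool) - natives)
    if n_aliens > len(candidates):
        raise ValueError(
            f"pool has only {len(candidates)} drawable species, "
            f"need {n_aliens}"
        )
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    sums = native_distance_sums(tree, natives)
    values = np.array([sums[sp] for sp in candidates]) / len(natives)
    return _draw_null_means(values, n_aliens, n_reps, rng)


def summarize_null(observed: float, nulls) -> dict:
    """ΔMPD, SES and inverse-variance weight from a null sample."""
    nulls = np.asarray(nulls, dtype=float)
    if nulls.size == 0:
        raise ValueError("empty null vector")
    mean = float(nulls.mean())
    sd = float(nulls.std(ddof=1)) if nulls.size > 1 else 0.0
    delta = observed - mean
    if sd > 0:
        ses = delta / sd
        weight = 1.0 / (sd * sd)
    else:
        ses = math.nan
        weight = math.nan
    return {
        "observed_mpd": float(observed),
        "null_mean": mean,
        "null_sd": sd,
        "delta_mpd": float(delta),
        "ses_mpd": ses,
        "weight": weight,
        "n_reps": int(nulls.size),
    }


def run_region_pools(
    tree: PhyloTree,
    region: RegionRecord,
    pools: list[PoolType],
    registry: SpeciesRegistry,
    continent_regions: dict[str, set[str]] | None = None,
    suitability: dict[str, set[str]] | None = None,
    n_reps: int = 1000,
    seed: int = 0,
) -> list[NullResult]:
    """All requested null models for one region.

    Native and alien sets are restricted to species on the tree (the
    usual silent restriction to phylogenetically resolvable species);
    regions left without at least one native and one alien are skipped
    with a logged reason and yield an empty list.  Each (region, pool)
    pair draws from its own :func:`substream` of the master seed.
    """
    tips = tree.tip_names
    natives = region.natives & tips
    aliens = region.aliens & tips
    if not natives or not aliens:
        log.warning(
            "skipping region %s: %d natives / %d aliens on tree",
            region.region_id, len(natives), len(aliens),
        )
        return []
    observed = crossgroup_mpd(tree, aliens, natives)
    sums = native_distance_sums(tree, natives)
    nb = len(natives)

    results = []
    for pool_type in pools:
        pool = build_pool(
            pool_type, region, registry,
            continent_regions=continent_regions, suitability=suitability,
        )
        candidates = sorted((pool & tips) - natives)
        if len(candidates) < len(aliens):
            raise ValueError(
                f"pool {pool_type.name} for region {region.region_id}: "
                f"only {len(candidates)} species on tree, fewer than the "
                f"{len(aliens)} observed aliens"
            )
        values = np.array([sums[sp] for sp in candidates]) / nb
        rng = substream(seed, region.region_id, pool_type.name)
        nulls = _draw_null_means(values, len(aliens), n_reps, rng)
        summary = summarize_null(observed, nulls)
        results.append(
            NullResult(
                region_id=region.region_id,
                pool=pool_type,
                n_native=nb,
                n_alien=len(aliens),
                **summary,
            )
        )
    return results


def results_to_frame(results: list[NullResult]) -> pd.DataFrame:
    """Flatten results to the region_results.csv layout."""
    rows = [
        {
            "region_id": r.region_id,
            "pool": r.pool.name,
            "n_native": r.n_native,
            "n_alien": r.n_alien,
            "observed_mpd": r.observed_mpd,
            "null_mean": r.null_mean,
            "null_sd": r.null_sd,
            "delta_mpd": r.delta_mpd,
            "ses_mpd": r.ses_mpd,
            "weight": r.weight,
            "n_reps": r.n_reps,
        }
        for r in results
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "region_id", "pool", "n_native", "n_alien", "observed_mpd",
            "null_mean", "null_sd", "delta_mpd", "ses_mpd", "weight",
            "n_reps",
        ],
    )
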