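"""Species registry and the six candidate alien source pools.

A regional null model needs to know which species *could* have arrived in
a region.  Six nested definitions of that candidate pool are supported,
from the most permissive (every species not native to the region) to the
most restrictive (species both climatically suitable for the region and
already naturalized somewhere on its continent).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

__all__ = [
    "PoolType",
    "SpeciesInfo",
    "SpeciesRegistry",
    "RegionRecord",
    "resolve_status_conflicts",
    "filter_regions",
    "build_pool",
]


class PoolType(enum.Enum):
    """The six candidate alien source pools, most to least permissive."""

    GLOBAL_NONNATIVE = "global_nonnative"
    ECON_USE_FLORA = "econ_use_flora"
    GLOBAL_NAT = "global_nat"
    CONTINENT_NAT = "continent_nat"
    CLIMATE_NAT = "climate_nat"
    CLIMATE_CONTINENT_NAT = "climate_continent_nat"

    @classmethod
    def parse(cls, name: str) -> "PoolType":
        key = name.strip().upper()
        try:
            return cls[key]
        except KeyError:
            valid = ", ".join(p.name for p in cls)
            raise ValueError(
                f"unknown pool {name!r}; valid pools: {valid}"
            ) from None


CLIMATE_POOLS = {PoolType.CLIMATE_NAT, PoolType.CLIMATE_CONTINENT_NAT}


@dataclass
class SpeciesInfo:
    genus: str
    family: str
    econ_use: bool = False
    native_regions: set[str] = field(default_factory=set)
    naturalized_regions: set[str] = field(default_factory=set)


@dataclass
class SpeciesRegistry:
    """Per-species taxonomy, economic-use flag and regional status sets."""

    species: dict[str, SpeciesInfo] = field(default_factory=dict)
    n_conflicts: int = 0

    def __contains__(self, sp: str) -> bool:
        return sp in self.species

    def __getitem__(self, sp: str) -> SpeciesInfo:
        return self.species[sp]

    def all_species(self) -> set[str]:
        return set(self.species)

    def naturalized_anywhere(self) -> set[str]:
        return {
            s for s, info in self.species.items()
            if info.naturalized_regions
        }

    def econ_use_species(self) -> set[str]:
        return {s for s, info in self.species.items() if info.econ_use}

    def naturalized_in_regions(self, region_ids: set[str]) -> set[str]:
        return {
            s for s, info in self.species.items()
            if info.naturalized_regions & region_ids
        }


@dataclass
class RegionRecord:
    """One analysis region: attributes plus its native and alien tip sets."""

    region_id: str
    area_km2: float
    latitude: float
    continent: str
    hm: float
    completeness: float = 1.0
    natives: set[str] = field(default_factory=set)
    aliens: set[str] = field(default_factory=set)

    def __post_init__(self):
        if self.area_km2 <= 0:
            raise ValueError(f"region {self.region_id}: area must be > 0")
        if not 0.0 <= self.hm <= 1.0:
            raise ValueError(
                f"region {self.region_id}: hm must be in [0, 1]"
            )
        if self.natives & self.aliens:
            raise ValueError(
                f"region {self.region_id}: native/alien sets overlap"
            )


def resolve_status_conflicts(
    records,
    rule: str = "native_wins",
    taxonomy=None,
    econ_use: set[str] | None = None,
) -> SpeciesRegistry:
    """Turn raw (region, species, status) records into a registry.

    A (region, species) pair listed both as native and as naturalized is a
    status conflict; the default rule keeps it native, the ``alien_wins``
    rule keeps it naturalized (the sensitivity variant).  The number of
    conflicts found is recorded on the registry.

    ``taxonomy`` (a mapping or :class:`~phylonat.tree.TaxonomyMap`) and
    ``econ_use`` fill in the per-species attributes when available.
    """
    if rule not in ("native_wins", "alien_wins"):
        raise ValueError("rule must be 'native_wins' or 'alien_wins'")
    native: dict[tuple[str, str], bool] = {}
    naturalized: dict[tuple[str, str], bool] = {}
    for region_id, sp, status in records:
        if status == "native":
            native[(region_id, sp)] = True
        elif status == "naturalized":
            naturalized[(region_id, sp)] = True
        else:
            raise ValueError(
                f"unknown status {status!r} for {sp!r} in {region_id!r}"
            )
    conflicts = set(native) & set(naturalized)
    for key in conflicts:
        if rule == "native_wins":
            del naturalized[key]
        else:
            del native[key]

    reg = SpeciesRegistry(n_conflicts=len(conflicts))
    econ_use = econ_use or set()

    def _info(sp: str) -> SpeciesInfo:
        if sp not in reg.species:
            genus, family = "", ""
            if taxonomy is not None:
                genus = taxonomy.species_to_genus.get(sp, "")
                family = taxonomy.genus_to_family.get(genus, "")
            reg.species[sp] = SpeciesInfo(
                genus=genus, family=family, econ_use=sp in econ_use
            )
        return reg.species[sp]

    for (region_id, sp) in native:
        _info(sp).native_regions.add(region_id)
    for (region_id, sp) in naturalized:
        _info(sp).naturalized_regions.add(region_id)
    return reg


def filter_regions(
    regions: list[RegionRecord], min_area: float
) -> list[RegionRecord]:
    """Keep regions strictly larger than ``min_area`` km², order preserved."""
    if min_area < 0:
        raise ValueError("min_area must be >= 0")
    return [r for r in regions if r.area_km2 > min_area]


def build_pool(
    pool: PoolType,
    region: RegionRecord,
    registry: SpeciesRegistry,
    continent_regions: dict[str, set[str]] | None = None,
    suitability: dict[str, set[str]] | None = None,
) -> set[str]:
    """Candidate alien species for one region under one pool definition.

    Every pool excludes the focal region's natives but retains its actual
    aliens (so the null model can re-draw them).  ``continent_regions``
    maps continent label → region ids (required for the continent pools);
    ``suitability`` maps species → climatically suitable region ids
    (required for the climate pools: species without an entry have an
    empty suitable set and drop out).
    """
    natives = region.natives
    if pool is PoolType.GLOBAL_NONNATIVE:
        out = registry.all_species() - natives
    elif pool is PoolType.ECON_USE_FLORA:
        out = (
            registry.econ_use_species() | registry.naturalized_anywhere()
        ) - natives
    elif pool is PoolType.GLOBAL_NAT:
        out = registry.naturalized_anywhere() - natives
    elif pool is PoolType.CONTINENT_NAT:
        if continent_regions is None:
            raise ValueError(
                "continent pools need the continent→regions mapping"
            )
        ids = continent_regions.get(region.continent, set())
        out = registry.naturalized_in_regions(ids) - natives
    elif pool in CLIMATE_POOLS:
        if suitability is None:
            raise ValueError(
                f"pool {pool.name} requires a suitability table"
            )
        glob = registry.naturalized_anywhere() - natives
        suited = {
            s for s in glob
            if region.region_id in suitability.get(s, set())
        }
        if pool is PoolType.CLIMATE_NAT:
            out = suited
        else:
            base = build_pool(
                PoolType.CONTINENT_NAT, region, registry, continent_regions
            )
            out = base & suited
    else:  # pragma: no cover
        raise ValueError(f"unknown pool {pool}")

    if len(out) < len(region.aliens):
        raise ValueError(
            f"pool {pool.name} for region {region.region_id} has "
            f"{len(out)} species, fewer than its {len(region.aliens)} "
            "observed aliens"
        )
    return out
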