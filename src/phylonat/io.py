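"""Plain-text interchange: reading and writing the pipeline's inputs.

A "world directory" holds:

    tree.nwk          Newick phylogeny with branch lengths
    species.csv       species, genus, family, econ_use (0/1)
    status.csv        region_id, species, status (native|naturalized)
    regions.csv       region_id, area_km2, latitude, continent, hm,
                      completeness
    climate.csv       region_id, cell_id, bio1..bio19
    occurrences.csv   species, cell_id
    truth.yaml        generator ground truth (synthetic worlds only)
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .pools import RegionRecord, SpeciesRegistry, resolve_status_conflicts
from .tree import PhyloTree, TaxonomyMap, parse_newick

__all__ = ["write_world", "WorldInputs", "load_world_inputs"]


def write_world(world, outdir) -> Path:
    """Write a synthetic world to a world directory (text files only)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "tree.nwk").write_text(world.tree.to_newick() + "\n")

    species = sorted(world.tree.tip_names)
    tax = world.taxonomy
    pd.DataFrame(
        {
            "species": species,
            "genus": [tax.species_to_genus[s] for s in species],
            "family": [
                tax.genus_to_family[tax.species_to_genus[s]]
                for s in species
            ],
            "econ_use": [
                int(world.registry[s].econ_use if s in world.registry else 0)
                for s in species
            ],
        }
    ).to_csv(out / "species.csv", index=False)

    pd.DataFrame(
        world.status_records(), columns=["region_id", "species", "status"]
    ).to_csv(out / "status.csv", index=False)

    pd.DataFrame(
        [
            {
                "region_id": r.region_id,
                "area_km2": r.area_km2,
                "latitude": r.latitude,
                "continent": r.continent,
                "hm": r.hm,
                "completeness": r.completeness,
            }
            for r in world.regions
        ]
    ).to_csv(out / "regions.csv", index=False)

    world.climate.to_csv(out / "climate.csv", index=False)
    world.occurrences.to_csv(out / "occurrences.csv", index=False)
    (out / "truth.yaml").write_text(
        yaml.safe_dump(world.truth, sort_keys=True)
    )
    return out


class WorldInputs:
    """Parsed pipeline inputs plus the derived registry and regions."""

    def __init__(
        self,
        tree: PhyloTree,
        taxonomy: TaxonomyMap,
        registry: SpeciesRegistry,
        regions: list[RegionRecord],
        climate: pd.DataFrame,
        occurrences: pd.DataFrame,
    ):
        self.tree = tree
        self.taxonomy = taxonomy
        self.registry = registry
        self.regions = regions
        self.climate = climate
        self.occurrences = occurrences

    @property
    def continent_regions(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for r in self.regions:
            out.setdefault(r.continent, set()).add(r.region_id)
        return out


def load_world_inputs(
    indir, conflict_rule: str = "native_wins"
) -> WorldInputs:
    """Read a world directory, resolving status conflicts per rule."""
    indir = Path(indir)
    tree = parse_newick((indir / "tree.nwk").read_text())
    species = pd.read_csv(indir / "species.csv")
    taxonomy = TaxonomyMap.from_frame(species)
    econ = set(species.loc[species["econ_use"].astype(int) == 1, "species"])
    status = pd.read_csv(indir / "status.csv")
    records = list(
        status[["region_id", "species", "status"]].itertuples(
            index=False, name=None
        )
    )
    registry = resolve_status_conflicts(
        records, rule=conflict_rule, taxonomy=taxonomy, econ_use=econ
    )

    attrs = pd.read_csv(indir / "regions.csv")
    regions = []
    for row in attrs.itertuples(index=False):
        rid = str(row.region_id)
        natives = {
            s for s, info in registry.species.items()
            if rid in info.native_regions
        }
        aliens = {
            s for s, info in registry.species.items()
            if rid in info.naturalized_regions
        }
        regions.append(
            RegionRecord(
                region_id=rid,
                area_km2=float(row.area_km2),
                latitude=float(row.latitude),
                continent=str(row.continent),
                hm=float(row.hm),
                completeness=float(row.completeness),
                natives=natives,
                aliens=aliens,
            )
        )
    climate = pd.read_csv(indir / "climate.csv")
    occurrences = pd.read_csv(indir / "occurrences.csv")
    return WorldInputs(tree, taxonomy, registry, regions, climate,
                       occurrences)
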