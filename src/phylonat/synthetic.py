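"""Synthetic-world generator: a self-contained stand-in for the global
floras, phylogeny, climate grids and naturalization records the analysis
pipeline consumes.

The generated world has the statistical structure the analysis assumes:

* an ultrametric pure-birth (Yule) phylogeny whose genera and families
  are monophyletic clades obtained by cutting the tree at two depths;
* a thermal niche optimum per species evolving by Brownian motion, so
  close relatives have similar climate tolerances (niche conservatism);
* regions on a latitudinal gradient with cell-level bioclim variables:
  temperature declines and seasonality increases with |latitude| while
  precipitation varies independently of latitude;
* native assemblages drawn by Gaussian environmental filtering around
  the region's climate position, with filter width *shrinking* poleward
  (phylogenetic clustering strengthens toward the poles);
* naturalization of non-native species drawn from a complementary
  log-log model whose linear predictor contains an MPD × |latitude|
  interaction plus species and region random effects.

Every stage is a pure function of (parameters, seed); ground-truth
parameters are stored with the world so recovery tests can compare
fitted against generating values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import dendropy
import numpy as np
import pandas as pd

from .climate import BIOCLIM_VARS
from .nullmodel import substream
from .pools import RegionRecord, SpeciesRegistry, resolve_status_conflicts
from .tree import PhyloTree, TaxonomyMap, native_distance_sums

__all__ = [
    "WorldParams",
    "SyntheticWorld",
    "simulate_tree",
    "simulate_niche_traits",
    "build_regions",
    "assemble_natives",
    "simulate_naturalizations",
    "generate_world",
]


@dataclass
class WorldParams:
    """Generator settings; defaults define the package's study conditions.

    Units: branch lengths and trait variance per unit time are arbitrary
    time-like units; latitude in degrees; temperature-like variables in
    °C-like units; areas in km².
    """

    n_species: int = 400
    birth_rate: float = 1.0
    n_genera: int = 60
    n_families: int = 20
    trait_sigma2: float = 1.0
    n_regions: int = 60
    cells_per_region: int = 10
    latitude_range: float = 60.0
    climate_noise_sd: float = 1.5
    precip_latitude_coefficient: float = 0.0
    richness_per_region: int = 80
    filtering_base_sd: float = 2.0
    filtering_latitude_coefficient: float = 0.025
    beta0: float = -2.2
    beta_mpd: float = 0.15
    beta_lat: float = 0.0
    beta_int: float = -0.35
    alien_filter_sd: float = 2.0
    sd_species: float = 0.3
    sd_region: float = 0.3
    econ_use_rate: float = 0.3
    hm_alpha: float = 1.5
    hm_beta: float = 3.0
    area_log_mean: float = 9.5
    area_log_sd: float = 1.0
    n_continents: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.n_species < 4:
            raise ValueError("n_species must be >= 4")
        if self.n_genera > self.n_species:
            raise ValueError("n_genera cannot exceed n_species")
        if self.n_families > self.n_genera:
            raise ValueError("n_families cannot exceed n_genera")
        for name in ("birth_rate", "trait_sigma2", "filtering_base_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_regions < 8:
            raise ValueError("n_regions must be >= 8")
        if self.richness_per_region >= self.n_species:
            raise ValueError(
                "richness_per_region must be smaller than n_species "
                "(otherwise no species is left to naturalize)"
            )


@dataclass
class SyntheticWorld:
    """A generated world plus the ground truth that produced it."""

    params: WorldParams
    tree: PhyloTree
    taxonomy: TaxonomyMap
    registry: SpeciesRegistry
    regions: list[RegionRecord]
    climate: pd.DataFrame
    occurrences: pd.DataFrame
    naturalization_table: pd.DataFrame
    optima: dict[str, float]
    truth: dict = field(default_factory=dict)

    @property
    def continent_regions(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for r in self.regions:
            out.setdefault(r.continent, set()).add(r.region_id)
        return out

    def status_records(self) -> list[tuple[str, str, str]]:
        recs = []
        for r in self.regions:
            recs += [(r.region_id, s, "native") for s in sorted(r.natives)]
            recs += [
                (r.region_id, s, "naturalized") for s in sorted(r.aliens)
            ]
        return recs


# ---------------------------------------------------------------------
# tree + taxonomy
# ---------------------------------------------------------------------


def _yule_events(
    birth_rate: float,
    rng: np.random.Generator,
    n_target: int | None,
    duration: float | None,
):
    """Crown-start Yule process: returns (split times, end time, n_tips)."""
    t, k = 0.0, 2
    splits = [0.0]  # crown split at time zero
    while True:
        dt = rng.exponential(1.0 / (birth_rate * k))
        if duration is not None and t + dt > duration:
            return splits, duration, k
        if n_target is not None and k == n_target:
            return splits, t + dt, k
        t += dt
        splits.append(t)
        k += 1


def simulate_tree(
    n_species: int,
    birth_rate: float = 1.0,
    seed: int = 0,
    n_genera: int | None = None,
    n_families: int | None = None,
    duration: float | None = None,
) -> tuple[PhyloTree, TaxonomyMap]:
    """Ultrametric pure-birth tree with monophyletic genera and families.

    The process starts at the crown (two lineages at time zero) and runs
    until ``n_species`` tips exist (then holds for one further
    exponential waiting time) or, when ``duration`` is given, for that
    fixed time span with a random tip count.  Genera and families are the
    clades cut by horizontal lines placed so that exactly ``n_genera``
    (``n_families``) lineages cross them.
    """
    rng = substream(seed, "tree")
    splits, t_end, n_tips = _yule_events(
        birth_rate, rng,
        None if duration is not None else n_species,
        duration,
    )

    # grow the topology: at each split a uniformly chosen active lineage
    # divides; nodes carry their birth time until closed.
    taxon_ns = dendropy.TaxonNamespace()
    dtree = dendropy.Tree(taxon_namespace=taxon_ns)
    root = dtree.seed_node
    root.birth = 0.0
    c1, c2 = dendropy.Node(), dendropy.Node()
    for c in (c1, c2):
        c.birth = 0.0
        root.add_child(c)
    active = [c1, c2]
    for t in splits[1:]:
        i = rng.integers(len(active))
        node = active[i]
        node.edge.length = t - node.birth
        kids = [dendropy.Node(), dendropy.Node()]
        for kid in kids:
            kid.birth = t
            node.add_child(kid)
        active[i] = kids[0]
        active.append(kids[1])
    width = len(str(len(active)))
    for j, node in enumerate(active):
        node.edge.length = t_end - node.birth
        node.taxon = taxon_ns.new_taxon(f"S{j + 1:0{width}d}")

    tree = PhyloTree(dtree)
    n_genera = min(n_genera or max(2, n_tips // 6), n_tips)
    n_families = min(n_families or max(2, n_genera // 3), n_genera)
    tax = _cut_taxonomy(tree, sorted(splits), t_end, n_genera, n_families)
    return tree, tax


def _cut_depth(splits: list[float], t_end: float, m: int) -> float:
    """A depth crossed by exactly ``m`` lineages (m-1 splits before it)."""
    lo = splits[m - 2]
    hi = splits[m - 1] if m - 1 < len(splits) else t_end
    return 0.5 * (lo + hi)


def _clades_at_depth(tree: PhyloTree, depth: float) -> list[list[str]]:
    clades = []
    stack = [(tree.dendropy_tree.seed_node, 0.0)]
    while stack:
        node, d0 = stack.pop()
        for child in node.child_nodes():
            d1 = d0 + child.edge.length
            if d1 > depth:
                clades.append(
                    [lf.taxon.label for lf in child.leaf_iter()]
                )
            else:
                stack.append((child, d1))
    return clades


def _cut_taxonomy(
    tree: PhyloTree,
    splits: list[float],
    t_end: float,
    n_genera: int,
    n_families: int,
) -> TaxonomyMap:
    genus_depth = _cut_depth(splits, t_end, n_genera)
    family_depth = _cut_depth(splits, t_end, n_families)
    genus_clades = _clades_at_depth(tree, genus_depth)
    family_clades = _clades_at_depth(tree, family_depth)
    sp2fam = {}
    for i, clade in enumerate(sorted(family_clades)):
        for sp in clade:
            sp2fam[sp] = f"F{i + 1:03d}"
    s2g, g2f = {}, {}
    for i, clade in enumerate(sorted(genus_clades)):
        genus = f"G{i + 1:04d}"
        for sp in clade:
            s2g[sp] = genus
        g2f[genus] = sp2fam[clade[0]]
    return TaxonomyMap(s2g, g2f)


# ---------------------------------------------------------------------
# traits, regions, assemblages
# ---------------------------------------------------------------------


def simulate_niche_traits(
    tree: PhyloTree, trait_sigma2: float, seed: int = 0
) -> dict[str, float]:
    """Brownian-motion thermal optima along the tree, root value 0."""
    if trait_sigma2 < 0:
        raise ValueError("trait_sigma2 must be >= 0")
    rng = substream(seed, "traits")
    values: dict[dendropy.Node, float] = {}
    dtree = tree.dendropy_tree
    values[dtree.seed_node] = 0.0
    for node in dtree.preorder_node_iter():
        if node is dtree.seed_node:
            continue
        step_var = trait_sigma2 * node.edge.length
        values[node] = values[node.parent_node] + (
            rng.normal(0.0, np.sqrt(step_var)) if step_var > 0 else 0.0
        )
    return {
        lf.taxon.label: values[lf] for lf in dtree.leaf_node_iter()
    }


def build_regions(
    params: WorldParams, seed: int = 0
) -> tuple[list[RegionRecord], pd.DataFrame]:
    """Regions on a latitude gradient plus their bioclim cell grid."""
    rng = substream(seed, "regions")
    n = params.n_regions
    width = len(str(n))
    lat = rng.uniform(-params.latitude_range, params.latitude_range, n)
    area = rng.lognormal(params.area_log_mean, params.area_log_sd, n)
    hm = rng.beta(params.hm_alpha, params.hm_beta, n)
    completeness = rng.uniform(0.4, 1.0, n)
    block = int(np.ceil(n / params.n_continents))
    regions = [
        RegionRecord(
            region_id=f"R{i + 1:0{width}d}",
            area_km2=float(area[i]),
            latitude=float(lat[i]),
            continent=f"C{i // block + 1}",
            hm=float(hm[i]),
            completeness=float(completeness[i]),
        )
        for i in range(n)
    ]

    rows = []
    noise = params.climate_noise_sd
    for i, reg in enumerate(regions):
        L = abs(reg.latitude)
        # region-level latent climate: temperature tracks latitude,
        # humidity is latitude-independent (plus an optional trend)
        temp_r = 28.0 - 0.45 * L + rng.normal(0.0, noise)
        humid_r = rng.normal(0.0, 1.0) + (
            params.precip_latitude_coefficient * L
        )
        for c in range(params.cells_per_region):
            e = rng.normal(0.0, noise, 19)
            bio = {}
            bio["bio1"] = temp_r + e[0]
            bio["bio2"] = 8.0 + 0.05 * L + 0.5 * e[1]
            bio["bio3"] = 60.0 - 0.5 * L + e[2]
            bio["bio4"] = 100.0 + 12.0 * L + 10.0 * e[3]
            bio["bio5"] = bio["bio1"] + 8.0 + 0.10 * L + 0.5 * e[4]
            bio["bio6"] = bio["bio1"] - 8.0 - 0.30 * L + 0.5 * e[5]
            bio["bio7"] = bio["bio5"] - bio["bio6"] + 0.5 * e[6]
            bio["bio8"] = bio["bio1"] + 2.0 + 0.5 * e[7]
            bio["bio9"] = bio["bio1"] - 2.0 + 0.5 * e[8]
            bio["bio10"] = bio["bio1"] + 4.0 + 0.5 * e[9]
            bio["bio11"] = bio["bio1"] - 4.0 + 0.5 * e[10]
            # precipitation block: log-normal-ish amounts (skewed on
            # purpose, to exercise the normalizing transforms)
            bio["bio12"] = float(
                np.exp(6.5 + 0.8 * humid_r + 0.25 * e[11])
            )
            bio["bio13"] = 0.18 * bio["bio12"] * np.exp(0.1 * e[12])
            bio["bio14"] = 0.02 * bio["bio12"] * np.exp(0.2 * e[13])
            bio["bio15"] = 55.0 - 12.0 * humid_r + 3.0 * e[14]
            bio["bio16"] = 0.45 * bio["bio12"] * np.exp(0.05 * e[15])
            bio["bio17"] = 0.08 * bio["bio12"] * np.exp(0.15 * e[16])
            bio["bio18"] = 0.30 * bio["bio12"] * np.exp(0.1 * e[17])
            bio["bio19"] = 0.15 * bio["bio12"] * np.exp(0.1 * e[18])
            rows.append(
                {
                    "region_id": reg.region_id,
                    "cell_id": f"{reg.region_id}_c{c + 1:02d}",
                    **{v: float(bio[v]) for v in BIOCLIM_VARS},
                }
            )
    return regions, pd.DataFrame(rows)


def region_niche_centers(
    climate: pd.DataFrame, optima: dict[str, float]
) -> dict[str, float]:
    """Each region's position on the thermal niche axis.

    The region-mean annual temperature (bio1) is z-scored across regions
    and rescaled to the dispersion of the species optima, putting regions
    and species on a common trait scale.
    """
    opt = np.array(list(optima.values()))
    s_opt = opt.std(ddof=0) or 1.0
    bio1 = climate.groupby("region_id")["bio1"].mean()
    z1 = (bio1 - bio1.mean()) / (bio1.std(ddof=0) or 1.0)
    return {rid: float(z1[rid]) * s_opt for rid in bio1.index}


def assemble_natives(
    regions: list[RegionRecord],
    optima: dict[str, float],
    climate: pd.DataFrame,
    params: WorldParams,
    seed: int = 0,
) -> None:
    """Fill each region's native set by Gaussian environmental filtering.

    Species s joins region r with probability proportional to
    ``exp(-(opt_s - mu_r)^2 / (2 sigma_r^2))`` where mu_r is the region's
    climate position on the niche axis and
    ``sigma_r = filtering_base_sd * exp(-filtering_latitude_coefficient *
    |lat_r|)``; a fixed number of natives per region is drawn without
    replacement under these weights, pinning mean richness at the target.
    """
    species = sorted(optima)
    opt = np.array([optima[s] for s in species])
    centers = region_niche_centers(climate, optima)
    k = min(params.richness_per_region, len(species))
    for reg in regions:
        rng = substream(seed, "natives", reg.region_id)
        mu = centers[reg.region_id]
        sigma = params.filtering_base_sd * np.exp(
            -params.filtering_latitude_coefficient * abs(reg.latitude)
        )
        logw = -((opt - mu) ** 2) / (2.0 * sigma**2)
        w = np.exp(logw - logw.max())
        w /= w.sum()
        idx = rng.choice(len(species), size=k, replace=False, p=w)
        reg.natives = {species[i] for i in idx}
        if not reg.natives:
            raise RuntimeError(
                f"region {reg.region_id} received no natives"
            )


def simulate_naturalizations(
    tree: PhyloTree,
    regions: list[RegionRecord],
    params: WorldParams,
    seed: int = 0,
    optima: dict[str, float] | None = None,
    climate: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Draw naturalization outcomes for every non-native (species, region).

    The linear predictor on the cloglog scale is
    ``beta0 + beta_mpd*z(MPD) + beta_lat*z(|lat|) + beta_int*z(MPD)*z(|lat|)
    + climate_term + u_species + v_region``, with z-scores taken over the
    candidate table.  When ``optima`` and ``climate`` are supplied and
    ``alien_filter_sd`` is finite, the climate term is
    ``-(opt_s - mu_r)^2 / (2 * alien_filter_sd^2)`` — aliens face a
    Gaussian climate filter like the natives but with a wider,
    latitude-independent tolerance, so naturalized species are
    climatically plausible where they establish.  Together with the
    poleward-tightening *native* filter this links ΔMPD to latitude:
    climate-matched aliens sit increasingly closer than random pool
    draws to natives wherever the native assemblage is tightly
    clustered around the regional climate, i.e. toward the poles.
    Region alien sets are updated in place and the full table (the
    species-level modelling input) is returned.
    """
    species = sorted(tree.tip_names)
    rng = substream(seed, "naturalization")
    u = dict(
        zip(species, rng.normal(0.0, params.sd_species, len(species)))
    )
    v = {
        reg.region_id: rng.normal(0.0, params.sd_region)
        for reg in regions
    }
    rows = []
    for reg in regions:
        sums = native_distance_sums(tree, reg.natives)
        nb = len(reg.natives)
        for sp in species:
            if sp in reg.natives:
                continue
            rows.append(
                (sp, reg.region_id, sums[sp] / nb, abs(reg.latitude))
            )
    table = pd.DataFrame(
        rows, columns=["species", "region_id", "mpd_to_natives",
                       "abs_latitude"],
    )
    zm = table["mpd_to_natives"].to_numpy()
    zm = (zm - zm.mean()) / (zm.std(ddof=0) or 1.0)
    zl = table["abs_latitude"].to_numpy()
    zl = (zl - zl.mean()) / (zl.std(ddof=0) or 1.0)
    climate_term = 0.0
    if (
        optima is not None and climate is not None
        and np.isfinite(params.alien_filter_sd)
        and params.alien_filter_sd > 0
    ):
        centers = region_niche_centers(climate, optima)
        mismatch = (
            table["species"].map(optima).to_numpy()
            - table["region_id"].map(centers).to_numpy()
        )
        climate_term = -(mismatch**2) / (2.0 * params.alien_filter_sd**2)
    eta = (
        params.beta0
        + params.beta_mpd * zm
        + params.beta_lat * zl
        + params.beta_int * zm * zl
        + climate_term
        + table["species"].map(u).to_numpy()
        + table["region_id"].map(v).to_numpy()
    )
    prob = 1.0 - np.exp(-np.exp(eta))
    draw_rng = substream(seed, "naturalization-draws")
    y = (draw_rng.random(len(table)) < prob).astype(int)
    if y.sum() == 0 or y.sum() == len(y):
        raise RuntimeError(
            "degenerate naturalization outcome (all 0 or all 1); "
            "adjust the beta parameters"
        )
    table["naturalized"] = y

    by_region = table[table["naturalized"] == 1].groupby("region_id")[
        "species"
    ]
    for reg in regions:
        aliens = (
            set(by_region.get_group(reg.region_id))
            if reg.region_id in by_region.groups else set()
        )
        if not aliens:
            # rare at default settings (climatically extreme regions):
            # re-draw this region's outcomes until at least one species
            # naturalizes, i.e. condition the region on being invaded
            rr = substream(seed, "naturalization-redraw", reg.region_id)
            mask = table["region_id"] == reg.region_id
            p = prob[mask.to_numpy()]
            for _ in range(50):
                y2 = (rr.random(p.size) < p).astype(int)
                if y2.sum() > 0:
                    break
            table.loc[mask, "naturalized"] = y2
            aliens = set(
                table.loc[mask & (table["naturalized"] == 1), "species"]
            )
        reg.aliens = aliens
    return table


def generate_world(params: WorldParams | None = None) -> SyntheticWorld:
    """Run the full generator chain and assemble the world object."""
    params = params or WorldParams()
    seed = params.seed
    tree, tax = simulate_tree(
        params.n_species, params.birth_rate, seed,
        n_genera=params.n_genera, n_families=params.n_families,
    )
    optima = simulate_niche_traits(tree, params.trait_sigma2, seed)
    regions, climate = build_regions(params, seed)
    assemble_natives(regions, optima, climate, params, seed)
    table = simulate_naturalizations(
        tree, regions, params, seed, optima=optima, climate=climate
    )

    flag_rng = substream(seed, "econ")
    species = sorted(tree.tip_names)
    econ = {
        sp for sp in species if flag_rng.random() < params.econ_use_rate
    }
    records = []
    for reg in regions:
        records += [(reg.region_id, s, "native") for s in sorted(reg.natives)]
        records += [
            (reg.region_id, s, "naturalized") for s in sorted(reg.aliens)
        ]
    registry = resolve_status_conflicts(
        records, rule="native_wins", taxonomy=tax, econ_use=econ
    )

    # occurrences: all cells of every region where the species occurs
    cells_by_region = climate.groupby("region_id")["cell_id"]
    occ_rows = []
    for reg in regions:
        cells = list(cells_by_region.get_group(reg.region_id))
        for sp in sorted(reg.natives | reg.aliens):
            occ_rows += [(sp, c) for c in cells]
    occurrences = pd.DataFrame(occ_rows, columns=["species", "cell_id"])

    prevalence = float(table["naturalized"].mean())
    truth = {**asdict(params), "realized_prevalence": prevalence}
    return SyntheticWorld(
        params=params,
        tree=tree,
        taxonomy=tax,
        registry=registry,
        regions=regions,
        climate=climate,
        occurrences=occurrences,
        naturalization_table=table,
        optima=optima,
        truth=truth,
    )
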