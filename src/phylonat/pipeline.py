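"""Pipeline orchestration: ingest → grafting → pools → null models →
climate PCA → suitability → regression layer, with a run manifest.

Defaults mirror the analysis conventions of the regional-flora study
design this package implements: 1000 null replicates, regions larger
than 5000 km², status conflicts resolved as native, absolute latitude,
cell-level PCA, all six source pools.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import climate as climate_mod
from . import stats as stats_mod
from .io import WorldInputs, load_world_inputs
from .nullmodel import results_to_frame, run_region_pools
from .pools import PoolType, filter_regions
from .tree import (
    PhyloTree,
    collapse_to_rank,
    graft_missing_species,
    native_distance_sums,
)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger(__name__)

ALL_POOLS = [p.name for p in PoolType]


class PipelineError(RuntimeError):
    """A stage failure, prefixed with the stage name."""


@dataclass
class PipelineConfig:
    input_dir: str = "."
    output_dir: str = "results"
    pools: list[str] = field(default_factory=lambda: list(ALL_POOLS))
    n_reps: int = 1000
    seed: int = 0
    min_area: float = 5000.0
    conflict_rule: str = "native_wins"
    tree_resolution: str = "full"      # full | genus
    latitude_mode: str = "absolute"    # absolute | signed
    pca_mode: str = "cell"             # cell | region
    suitability_source: str = "envelope"  # envelope | <path to CSV>
    glmm_structure: str = "full"       # full | intercepts_only
    run_glmm: bool = True
    #: optional per-variable transform overrides for the climate PCA,
    #: e.g. {"bio12": "log1p_shift"}; unlisted variables use the fitted
    #: power transform
    pca_transforms: dict | None = None

    def __post_init__(self):
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        self.pools = [PoolType.parse(p).name for p in self.pools]
        if self.tree_resolution not in ("full", "genus"):
            raise ValueError("tree_resolution must be 'full' or 'genus'")
        if self.latitude_mode not in ("absolute", "signed"):
            raise ValueError("latitude_mode must be 'absolute' or 'signed'")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


def _lat_column(regions_df: pd.DataFrame, mode: str) -> np.ndarray:
    lat = regions_df["latitude"].to_numpy(float)
    return np.abs(lat) if mode == "absolute" else lat


# ------------------------------------------------------------------
# stages (each usable on its own; run_pipeline sequences them)
# ------------------------------------------------------------------


def stage_ingest(config: PipelineConfig) -> WorldInputs:
    return load_world_inputs(config.input_dir, config.conflict_rule)


def stage_graft(inputs: WorldInputs) -> dict:
    """Place registry species missing from the tree; report counts."""
    missing = sorted(inputs.registry.all_species() - inputs.tree.tip_names)
    if not missing:
        return {"added_at_genus": 0, "added_at_family": 0}
    tree, report = graft_missing_species(
        inputs.tree, inputs.taxonomy, missing
    )
    inputs.tree = tree
    return {
        "added_at_genus": report.added_at_genus,
        "added_at_family": report.added_at_family,
    }


def stage_suitability(
    inputs: WorldInputs, config: PipelineConfig
) -> tuple[dict[str, set[str]], pd.DataFrame]:
    if config.suitability_source == "envelope":
        table, report = climate_mod.suitability_table(
            inputs.occurrences,
            inputs.climate,
            species_list=sorted(inputs.registry.naturalized_anywhere()),
            seed=config.seed,
        )
        return table, report
    ext = pd.read_csv(config.suitability_source)
    table: dict[str, set[str]] = {}
    for sp, rid in ext[["species", "region_id"]].itertuples(
        index=False, name=None
    ):
        table.setdefault(sp, set()).add(str(rid))
    report = pd.DataFrame(
        {"species": sorted(table), "status": "external"}
    )
    return table, report


def stage_null(
    inputs: WorldInputs,
    config: PipelineConfig,
    suitability: dict[str, set[str]] | None,
) -> tuple[pd.DataFrame, list[str]]:
    pools = [PoolType.parse(p) for p in config.pools]
    regions = filter_regions(inputs.regions, config.min_area)
    results, skipped = [], []
    for reg in regions:
        for pool in pools:
            try:
                res = run_region_pools(
                    inputs.tree, reg, [pool], inputs.registry,
                    continent_regions=inputs.continent_regions,
                    suitability=suitability,
                    n_reps=config.n_reps, seed=config.seed,
                )
            except ValueError as exc:
                skipped.append(f"{reg.region_id}/{pool.name}: {exc}")
                continue
            if not res:
                skipped.append(
                    f"{reg.region_id}/{pool.name}: no natives or aliens "
                    "on the tree"
                )
            results.extend(res)
    return results_to_frame(results), skipped


def stage_pca(
    inputs: WorldInputs, config: PipelineConfig
) -> tuple[climate_mod.PcaModel, pd.DataFrame]:
    transforms = None
    if config.pca_transforms:
        transforms = {
            var: climate_mod.TransformSpec(name)
            for var, name in config.pca_transforms.items()
        }
    pca = climate_mod.fit_climate_pca(
        inputs.climate, transforms=transforms, mode=config.pca_mode
    )
    scores = climate_mod.region_scores_frame(pca, inputs.climate)
    return pca, scores


def stage_species_table(
    tree: PhyloTree, regions, min_area: float
) -> pd.DataFrame:
    """One row per (species on tree, region) with the species not native."""
    rows = []
    for reg in filter_regions(regions, min_area):
        natives = reg.natives & tree.tip_names
        if not natives:
            continue
        sums = native_distance_sums(tree, natives)
        nb = len(natives)
        for sp in sorted(tree.tip_names - natives):
            rows.append(
                {
                    "species": sp,
                    "region_id": reg.region_id,
                    "mpd_to_natives": sums[sp] / nb,
                    "abs_latitude": abs(reg.latitude),
                    "naturalized": int(sp in reg.aliens),
                }
            )
    return pd.DataFrame(rows)


def _fits_to_rows(name: str, fit: stats_mod.ModelFit) -> list[dict]:
    rows = []
    for term, rec in fit.coef.iterrows():
        row = {
            "model": name,
            "method": fit.method,
            "term": term,
            "estimate": rec["estimate"],
            "se": rec["se"],
            "stat": rec["stat"],
            "pvalue": rec["pvalue"],
            "std_estimate": rec.get("std_estimate", np.nan),
            "std_se": rec.get("std_se", np.nan),
            "adj_r2": np.nan if fit.adj_r2 is None else fit.adj_r2,
            "converged": fit.converged,
        }
        rows.append(row)
    return rows


def stage_stats(
    inputs: WorldInputs,
    config: PipelineConfig,
    region_results: pd.DataFrame,
    region_scores: pd.DataFrame,
    species_table: pd.DataFrame | None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, stats_mod.ModelFit]]:
    attrs = pd.DataFrame(
        [
            {
                "region_id": r.region_id,
                "latitude": r.latitude,
                "continent": r.continent,
                "hm": r.hm,
                "completeness": r.completeness,
            }
            for r in inputs.regions
        ]
    )
    base = (
        region_results.merge(attrs, on="region_id")
        .merge(region_scores, on="region_id")
    )
    base["lat"] = _lat_column(base, config.latitude_mode)

    fits: dict[str, stats_mod.ModelFit] = {}
    curves: list[pd.DataFrame] = []

    def _add_curves(name, fit, focal, quantiles=(0.1, 0.5, 0.9),
                    fix_name="hm"):
        for q in quantiles:
            cur = stats_mod.partial_predictions(
                fit, focal, fix={fix_name: q}
            )
            cur.insert(0, "model", name)
            cur["fix_name"] = fix_name
            cur["fix_quantile"] = q
            curves.append(
                cur[["model", "focal", focal, "fix_name", "fix_quantile",
                     "prediction"]].rename(columns={focal: "focal_value"})
            )

    first_pool = config.pools[0]
    mpd_df = base[base["pool"] == first_pool]
    fits["mpd~lat"] = stats_mod.fit_weighted_linear(
        mpd_df["observed_mpd"], {"lat": mpd_df["lat"]}
    )
    fits["mpd~lat*hm"] = stats_mod.fit_interaction_model(
        mpd_df["observed_mpd"], mpd_df["lat"], mpd_df["hm"]
    )
    _add_curves("mpd~lat*hm", fits["mpd~lat*hm"], "latitude")
    fits["mpd~climate*hm"] = stats_mod.fit_lmm_climate(
        mpd_df["observed_mpd"], mpd_df["pc_temp"], mpd_df["pc_prec"],
        mpd_df["hm"], mpd_df["continent"],
    )
    for focal in ("pc_temp", "pc_prec"):
        _add_curves("mpd~climate*hm", fits["mpd~climate*hm"], focal)

    for pool in config.pools:
        sub = base[base["pool"] == pool]
        w = sub["weight"].to_numpy(float)
        usable = np.isfinite(w) & (w > 0)
        sub = sub[usable]
        w = w[usable]
        name = f"delta_mpd[{pool}]~lat"
        fits[name] = stats_mod.fit_weighted_linear(
            sub["delta_mpd"], {"lat": sub["lat"]}, weights=w
        )
        name_i = f"delta_mpd[{pool}]~lat*hm"
        fits[name_i] = stats_mod.fit_interaction_model(
            sub["delta_mpd"], sub["lat"], sub["hm"], weights=w
        )
        _add_curves(name_i, fits[name_i], "latitude")
        name_c = f"delta_mpd[{pool}]~climate*hm"
        fits[name_c] = stats_mod.fit_lmm_climate(
            sub["delta_mpd"], sub["pc_temp"], sub["pc_prec"], sub["hm"],
            sub["continent"], weights=w,
        )

    if species_table is not None and len(species_table):
        glmm = stats_mod.fit_glmm_naturalization(
            species_table, random_structure=config.glmm_structure
        )
        fits["naturalization~mpd*lat"] = glmm
        for q in (0.1, 0.5, 0.9):
            latval = float(species_table["abs_latitude"].quantile(q))
            cur = stats_mod.partial_predictions(
                glmm, "mpd_to_natives", fix_values={"abs_latitude": latval}
            )
            cur.insert(0, "model", "naturalization~mpd*lat")
            cur["fix_name"] = "abs_latitude"
            cur["fix_quantile"] = q
            curves.append(
                cur[["model", "focal", "mpd_to_natives", "fix_name",
                     "fix_quantile", "prediction"]].rename(
                    columns={"mpd_to_natives": "focal_value"}
                )
            )

    fit_rows = []
    for name, fit in fits.items():
        fit_rows.extend(_fits_to_rows(name, fit))
    model_fits = pd.DataFrame(fit_rows)
    partial = (
        pd.concat(curves, ignore_index=True)
        if curves else pd.DataFrame(
            columns=["model", "focal", "focal_value", "fix_name",
                     "fix_quantile", "prediction"]
        )
    )
    return model_fits, partial, fits


# ------------------------------------------------------------------
# the full run
# ------------------------------------------------------------------


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages, writing the result bundle to the output dir.

    Outputs: region_results.csv, naturalization_table.csv,
    model_fits.csv, partial_predictions.csv, suitability.csv (when
    computed), region_scores.csv and manifest.yaml.  Any stage error
    aborts with a stage-named :class:`PipelineError`; the manifest then
    records the run as incomplete.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": asdict(config),
        "seed": config.seed,
        "complete": False,
        "stages": {},
        "skipped_regions": [],
        "versions": _versions(),
    }
    artifacts: dict = {}

    def _stage(name, fn, *args, **kwargs):
        t0 = time.perf_counter()
        try:
            result = fn(*args, **kwargs)
        except Exception as exc:
            manifest["stages"][name] = {
                "status": "failed", "error": str(exc),
            }
            _write_manifest(out, manifest)
            raise PipelineError(f"stage {name}: {exc}") from exc
        manifest["stages"][name] = {
            "status": "ok",
            "seconds": round(time.perf_counter() - t0, 3),
        }
        return result

    inputs = _stage("ingest", stage_ingest, config)
    manifest["stages"]["ingest"]["n_regions"] = len(inputs.regions)
    graft_report = _stage("graft", stage_graft, inputs)
    manifest["graft"] = graft_report
    if config.tree_resolution == "genus":
        inputs.tree = _stage(
            "collapse", collapse_to_rank, inputs.tree, inputs.taxonomy,
            "genus",
        )

    suitability = None
    need_climate_pools = any(
        PoolType.parse(p) in
        (PoolType.CLIMATE_NAT, PoolType.CLIMATE_CONTINENT_NAT)
        for p in config.pools
    )
    if need_climate_pools:
        suitability, suit_report = _stage(
            "suitability", stage_suitability, inputs, config
        )
        suit_rows = [
            {"species": sp, "region_id": rid}
            for sp in sorted(suitability)
            for rid in sorted(suitability[sp])
        ]
        pd.DataFrame(
            suit_rows, columns=["species", "region_id"]
        ).to_csv(out / "suitability.csv", index=False)
        suit_report.to_csv(out / "suitability_report.csv", index=False)
        artifacts["suitability"] = suitability

    region_results, skipped = _stage(
        "null_model", stage_null, inputs, config, suitability
    )
    manifest["skipped_regions"] = skipped
    for reason in skipped:
        log.warning("skipped region: %s", reason)
    region_results.to_csv(out / "region_results.csv", index=False)

    pca, region_scores = _stage("pca", stage_pca, inputs, config)
    region_scores.to_csv(out / "region_scores.csv", index=False)
    manifest["pca_explained"] = [
        round(float(v), 6) for v in pca.explained[:4]
    ]

    species_table = None
    if config.run_glmm:
        species_table = _stage(
            "species_table", stage_species_table, inputs.tree,
            inputs.regions, config.min_area,
        )
        species_table.to_csv(
            out / "naturalization_table.csv", index=False
        )

    model_fits, partial, fits = _stage(
        "stats", stage_stats, inputs, config, region_results,
        region_scores, species_table,
    )
    model_fits.to_csv(out / "model_fits.csv", index=False)
    partial.to_csv(out / "partial_predictions.csv", index=False)

    manifest["complete"] = True
    _write_manifest(out, manifest)
    artifacts.update(
        inputs=inputs, region_results=region_results, pca=pca,
        region_scores=region_scores, species_table=species_table,
        model_fits=model_fits, partial_predictions=partial, fits=fits,
        manifest=manifest,
    )
    return artifacts


def _write_manifest(out: Path, manifest: dict) -> None:
    (out / "manifest.yaml").write_text(
        yaml.safe_dump(manifest, sort_keys=False)
    )


def _versions() -> dict:
    import dendropy
    import scipy
    import sklearn
    import statsmodels

    from . import __version__

    return {
        "phylonat": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "statsmodels": statsmodels.__version__,
        "scikit-learn": sklearn.__version__,
        "dendropy": dendropy.__version__,
    }
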