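"""Climate PCA and the envelope suitability stage.

A PCA over the 19 bioclim variables yields PC_Temp (axis 1, warm = high)
and PC_Prec (axis 2, humid = high).  Per species, a Mahalanobis climate
envelope over six bioclim variables scores every grid cell; models with
held-out AUC > 0.7 are kept and thresholded at maximum training
sensitivity + specificity, and a region is climatically suitable when at
least one of its cells reaches the threshold.
"""

import numpy as np

import phylonat as pn

world = pn.generate_world(pn.WorldParams(
    n_species=150, n_genera=30, n_families=10, n_regions=40,
    cells_per_region=6, richness_per_region=40, seed=1,
))

pca = pn.fit_climate_pca(world.climate)
print("variance explained: PC_Temp {:.1%}, PC_Prec {:.1%}".format(
    pca.explained[0], pca.explained[1]))
scores = pn.climate.region_scores_frame(pca, world.climate)
alat = {r.region_id: abs(r.latitude) for r in world.regions}
r = np.corrcoef(
    scores["pc_temp"], [alat[i] for i in scores["region_id"]]
)[0, 1]
print(f"Pearson r(PC_Temp, |latitude|) = {r:.3f}")
# strongly negative: high PC_Temp marks warm, low-latitude regions

table, report = pn.suitability_table(
    world.occurrences, world.climate,
    species_list=sorted(world.registry.naturalized_anywhere()), seed=0,
)
print("\nsuitability models:", report["status"].value_counts().to_dict())
kept = report[report["status"] == "retained"]
print("median held-out AUC of retained models:",
      round(float(kept["auc_test"].median()), 3))
sizes = [len(v) for v in table.values()]
print(f"suitable regions per species: mean {np.mean(sizes):.1f} "
      f"of {len(world.regions)}")
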