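"""Cross-group phylogenetic distance on a toy tree, plus grafting.

MPD between an alien set A and native set B is the mean patristic
distance over all cross pairs; MNTD is the mean distance from each alien
to its nearest native.  Species missing from a phylogeny are grafted at
the crown of their genus (or family) without breaking ultrametricity.
"""

import phylonat as pn
from phylonat.tree import TaxonomyMap

tree = pn.parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
print("tree:", pn.write_newick(tree))
print("MPD({A,B} vs {C,D}) =", pn.crossgroup_mpd(tree, {"A", "B"},
                                                 {"C", "D"}))
print("MNTD({A} vs {B,C}) =", pn.crossgroup_mntd(tree, {"A"},
                                                 {"B", "C"}))
# every cross pair is separated by the two depth-1 subtrees: distance 4

tax = TaxonomyMap(
    {"A": "G1", "B": "G1", "C": "G2", "D": "G2", "X": "G1"},
    {"G1": "F1", "G2": "F1"},
)
grafted, report = pn.graft_missing_species(tree, tax, ["X"])
print("\ngrafted X at:", report.placements["X"],
      "| tree:", pn.write_newick(grafted))
print("depths all equal:", grafted.is_ultrametric())
# X joins its congeners at the crown of G1 with a pendant edge of
# length 1, so the tree stays ultrametric (all tips at depth 2)
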