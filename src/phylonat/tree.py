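"""Phylogenetic backbone: Newick I/O, taxonomy-guided grafting, and
cross-group distance statistics.

The central quantity of the package is the cross-group mean pairwise
phylogenetic (patristic) distance between an alien species set A and a
native species set B on a rooted tree with branch lengths:

    MPD(A, B) = (1 / |A||B|) * sum_{a in A, b in B} d(a, b)

where d is the sum of branch lengths on the path between two tips.  MPD is
computed by edge contribution — each edge contributes its length times the
number of alien/native pairs whose path crosses it — which is O(n) per
evaluation instead of O(|A||B|) and is exactly equal to the brute-force
patristic-matrix mean.  The companion statistic MNTD (mean distance from
each alien to its nearest native) is provided as a utility.

Trees are stored as :class:`dendropy.Tree` objects wrapped in
:class:`PhyloTree`, which adds validation (unique tip labels, non-negative
edge lengths) and cached indices.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "PhyloTree",
    "TaxonomyMap",
    "GraftReport",
    "parse_newick",
    "write_newick",
    "graft_missing_species",
    "collapse_to_rank",
    "prune_tips",
    "crossgroup_mpd",
    "crossgroup_mntd",
    "native_distance_sums",
    "native_min_distances",
    "patristic_matrix",
]


class NewickParseError(ValueError):
    """Raised for malformed Newick input."""


class GraftError(ValueError):
    """Raised when species cannot be placed on the tree."""


class PhyloTree:
    """A rooted phylogeny with branch lengths and uniquely named tips.

    Thin wrapper over :class:`dendropy.Tree`; construction validates that
    tip labels are unique and that every non-root edge carries a
    non-negative length.
    """

    def __init__(self, dtree: dendropy.Tree):
        dtree.is_rooted = True  # trees here are rooted; stop derooting
        self._tree = dtree
        self._validate()
        self._leaf_index = {
            leaf.taxon.label: leaf for leaf in dtree.leaf_node_iter()
        }

    # -- construction / validation ------------------------------------

    def _validate(self) -> None:
        labels = []
        for leaf in self._tree.leaf_node_iter():
            if leaf.taxon is None or not leaf.taxon.label:
                raise ValueError("unnamed tip in tree")
            labels.append(leaf.taxon.label)
        dupes = {x for x in labels if labels.count(x) > 1} if len(
            set(labels)
        ) != len(labels) else set()
        if dupes:
            raise ValueError(f"duplicate tip names: {sorted(dupes)}")
        root = self._tree.seed_node
        for node in self._tree.preorder_node_iter():
            if node is root:
                continue
            if node.edge.length is None:
                raise ValueError(
                    "missing branch length on a non-root edge"
                )
            if node.edge.length < 0:
                raise ValueError("negative branch length")

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def tip_names(self) -> set[str]:
        return set(self._leaf_index)

    @property
    def n_tips(self) -> int:
        return len(self._leaf_index)

    def copy(self) -> "PhyloTree":
        return PhyloTree(self._tree.clone(depth=1))

    # -- geometry ------------------------------------------------------

    def tip_depths(self) -> dict[str, float]:
        """Root-to-tip path lengths, keyed by tip name."""
        depths: dict[str, float] = {}
        stack = [(self._tree.seed_node, 0.0)]
        while stack:
            node, d = stack.pop()
            if node.is_leaf():
                depths[node.taxon.label] = d
            for child in node.child_nodes():
                stack.append((child, d + child.edge.length))
        return depths

    def height(self) -> float:
        """Maximum root-to-tip depth."""
        return max(self.tip_depths().values())

    def is_ultrametric(self, rel_tol: float = 1e-9) -> bool:
        depths = np.asarray(list(self.tip_depths().values()))
        h = depths.max()
        if h == 0:
            return True
        return bool(np.ptp(depths) <= rel_tol * h)

    def node_heights(self) -> dict[dendropy.Node, float]:
        """Distance from each node down to its deepest descendant tip."""
        heights: dict[dendropy.Node, float] = {}
        for node in self._tree.postorder_node_iter():
            if node.is_leaf():
                heights[node] = 0.0
            else:
                heights[node] = max(
                    heights[c] + c.edge.length for c in node.child_nodes()
                )
        return heights

    # -- I/O -----------------------------------------------------------

    def to_newick(self) -> str:
        s = self._tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
        )
        return s.strip() + ("" if s.strip().endswith(";") else ";")

    def __repr__(self) -> str:  # pragma: no cover
        return f"<PhyloTree with {self.n_tips} tips>"


@dataclass(frozen=True)
class TaxonomyMap:
    """Species → genus and genus → family lookup.

    Every species maps to exactly one genus and every genus to exactly one
    family (enforced by the dict structure; inconsistent inputs raise at
    construction via :meth:`from_frame`).
    """

    species_to_genus: dict[str, str]
    genus_to_family: dict[str, str]

    @classmethod
    def from_frame(cls, df) -> "TaxonomyMap":
        """Build from a table with columns species, genus, family."""
        s2g: dict[str, str] = {}
        g2f: dict[str, str] = {}
        for sp, gen, fam in zip(df["species"], df["genus"], df["family"]):
            if sp in s2g and s2g[sp] != gen:
                raise ValueError(f"species {sp!r} mapped to two genera")
            if gen in g2f and g2f[gen] != fam:
                raise ValueError(f"genus {gen!r} mapped to two families")
            s2g[sp] = gen
            g2f[gen] = fam
        return cls(s2g, g2f)

    def genus_of(self, species: str) -> str:
        try:
            return self.species_to_genus[species]
        except KeyError:
            raise KeyError(f"species {species!r} not in taxonomy") from None

    def family_of_species(self, species: str) -> str:
        return self.genus_to_family[self.genus_of(species)]


@dataclass
class GraftReport:
    """Bookkeeping for a grafting pass."""

    added_at_genus: int = 0
    added_at_family: int = 0
    placements: dict[str, str] = field(default_factory=dict)


def parse_newick(text: str) -> PhyloTree:
    """Parse a Newick string (branch lengths required, polytomies allowed)."""
    try:
        dtree = dendropy.Tree.get(
            file=io.StringIO(text),
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickParseError(f"malformed Newick: {exc}") from exc
    return PhyloTree(dtree)


def write_newick(tree: PhyloTree) -> str:
    return tree.to_newick()


# ---------------------------------------------------------------------
# grafting and rank collapse
# ---------------------------------------------------------------------


def _tips_by_rank(tree: PhyloTree, tax: TaxonomyMap):
    """Map genus → tip nodes and family → tip nodes for mapped tips."""
    by_genus: dict[str, list] = {}
    by_family: dict[str, list] = {}
    for name, leaf in tree._leaf_index.items():
        gen = tax.species_to_genus.get(name)
        if gen is None:
            continue
        by_genus.setdefault(gen, []).append(leaf)
        fam = tax.genus_to_family.get(gen)
        if fam is not None:
            by_family.setdefault(fam, []).append(leaf)
    return by_genus, by_family


def _crown(dtree: dendropy.Tree, nodes: list) -> dendropy.Node:
    """MRCA by ancestor walk (robust to ongoing tree surgery, unlike
    bipartition-based lookups)."""
    if len(nodes) == 1:
        return nodes[0]

    def ancestors(node):
        out = []
        while node is not None:
            out.append(node)
            node = node.parent_node
        return out

    paths = [ancestors(n) for n in nodes]
    common = set(paths[0])
    for p in paths[1:]:
        common &= set(p)
    for nd in paths[0]:  # ordered tip → root: first hit is deepest
        if nd in common:
            return nd
    raise RuntimeError("nodes share no ancestor")  # pragma: no cover


def _node_height(node: dendropy.Node) -> float:
    heights: dict[dendropy.Node, float] = {}
    for nd in node.postorder_iter():
        if nd.is_leaf():
            heights[nd] = 0.0
        else:
            heights[nd] = max(
                heights[c] + c.edge.length for c in nd.child_nodes()
            )
    return heights[node]


def _attach_tip(
    dtree: dendropy.Tree,
    at: dendropy.Node,
    label: str,
    monotypic_split: float,
) -> dendropy.Node:
    """Attach a new pendant tip so that the tree stays ultrametric.

    At an internal node the pendant edge length equals the node's height
    (distance down to the tip level).  If the attachment point is itself a
    tip (single in-tree representative of the rank) its pendant edge is
    split at ``monotypic_split`` of its length and the new tip hangs from
    the inserted node.
    """
    taxon = dtree.taxon_namespace.new_taxon(label=label)
    if at.is_leaf():
        parent = at.parent_node
        if parent is None:
            raise GraftError(
                f"cannot graft {label!r}: attachment tip is the entire tree"
            )
        stem = at.edge.length
        split = monotypic_split * stem
        mid = dendropy.Node()
        parent.remove_child(at)
        parent.add_child(mid)
        mid.edge.length = stem - split
        mid.add_child(at)
        at.edge.length = split
        new = mid.new_child(taxon=taxon, edge_length=split)
    else:
        h = _node_height(at)
        new = at.new_child(taxon=taxon, edge_length=h)
    return new


def graft_missing_species(
    tree: PhyloTree,
    tax: TaxonomyMap,
    targets: list[str],
    monotypic_split: float = 0.5,
) -> tuple[PhyloTree, GraftReport]:
    """Add missing species at the crown of their genus, else family.

    Each target is attached as a new pendant tip at the most recent common
    ancestor of the tips already assigned to its genus; when the genus has
    no tips at all, at the crown of its family.  Pendant edge lengths equal
    the attachment node's height so that an ultrametric input stays
    ultrametric.  Targets are processed in order, so later congeners of an
    earlier-grafted species attach next to it.

    Raises :class:`GraftError` (listing all unplaceable species) when any
    target's family has no representative on the tree; no partial tree is
    returned in that case.
    """
    if not 0.0 < monotypic_split < 1.0:
        raise ValueError("monotypic_split must be in (0, 1)")
    out = tree.copy()
    dtree = out.dendropy_tree
    by_genus, by_family = _tips_by_rank(out, tax)
    report = GraftReport()
    unplaceable: list[str] = []

    for sp in targets:
        if sp in out._leaf_index or any(
            sp == n.taxon.label
            for nodes in by_genus.values()
            for n in nodes
        ):
            raise GraftError(f"target {sp!r} already present on the tree")
        genus = tax.genus_of(sp)
        family = tax.genus_to_family[genus]
        genus_tips = by_genus.get(genus, [])
        family_tips = by_family.get(family, [])
        if genus_tips:
            at = _crown(dtree, genus_tips)
            placed = "genus"
        elif family_tips:
            at = _crown(dtree, family_tips)
            placed = "family"
        else:
            unplaceable.append(sp)
            continue
        new = _attach_tip(dtree, at, sp, monotypic_split)
        by_genus.setdefault(genus, []).append(new)
        by_family.setdefault(family, []).append(new)
        report.placements[sp] = placed
        if placed == "genus":
            report.added_at_genus += 1
        else:
            report.added_at_family += 1

    if unplaceable:
        raise GraftError(
            "no tree representative for the families of: "
            + ", ".join(sorted(unplaceable))
        )
    return PhyloTree(dtree), report


def collapse_to_rank(
    tree: PhyloTree, tax: TaxonomyMap, rank: str
) -> PhyloTree:
    """Reduce within-rank resolution: every species becomes a pendant tip
    at the crown node of its genus (or family).

    Ranks with a single in-tree tip are left untouched (their crown is the
    tip itself), which makes the operation idempotent.  Ultrametricity is
    preserved because pendant lengths equal the crown node's height.
    """
    if rank not in ("genus", "family"):
        raise ValueError("rank must be 'genus' or 'family'")
    out = tree.copy()
    dtree = out.dendropy_tree

    groups: dict[str, list] = {}
    for name, leaf in out._leaf_index.items():
        if name not in tax.species_to_genus:
            raise ValueError(f"tip {name!r} missing from taxonomy")
        genus = tax.species_to_genus[name]
        key = genus if rank == "genus" else tax.genus_to_family[genus]
        groups.setdefault(key, []).append(leaf)

    # Crown nodes and heights must be fixed before any surgery.
    plans = []
    for key, leaves in groups.items():
        if len(leaves) < 2:
            continue
        crown = _crown(dtree, leaves)
        plans.append((crown, _node_height(crown), leaves))

    for crown, h, leaves in plans:
        labels = [lf.taxon.label for lf in leaves]
        for lf in leaves:
            lf.parent_node.remove_child(lf)
        for label in labels:
            taxon = next(
                t for t in dtree.taxon_namespace if t.label == label
            )
            crown.new_child(taxon=taxon, edge_length=h)

    # Drop leafless internal remnants, then merge single-child chains.
    changed = True
    while changed:
        changed = False
        for node in list(dtree.postorder_node_iter()):
            if node.taxon is None and not node.child_nodes() and (
                node.parent_node is not None
            ):
                node.parent_node.remove_child(node)
                changed = True
    dtree.suppress_unifurcations()
    return PhyloTree(dtree)


def prune_tips(tree: PhyloTree, names: list[str]) -> PhyloTree:
    """Remove the named tips, merging the resulting single-child edges."""
    missing = set(names) - tree.tip_names
    if missing:
        raise ValueError(f"tips not on tree: {sorted(missing)}")
    dtree = tree.copy().dendropy_tree
    taxa = [t for t in dtree.taxon_namespace if t.label in set(names)]
    dtree.prune_taxa(taxa, suppress_unifurcations=True)
    return PhyloTree(dtree)


# ---------------------------------------------------------------------
# cross-group distances
# ---------------------------------------------------------------------


def _check_sets(tree: PhyloTree, aliens, natives):
    a, b = set(aliens), set(natives)
    if not a or not b:
        raise ValueError("alien and native sets must both be non-empty")
    if a & b:
        raise ValueError(
            f"alien and native sets overlap: {sorted(a & b)[:5]}"
        )
    unknown = (a | b) - tree.tip_names
    if unknown:
        raise ValueError(f"names not on tree: {sorted(unknown)[:5]}")
    return a, b


def crossgroup_mpd(tree: PhyloTree, aliens, natives) -> float:
    """Mean pairwise patristic distance between two disjoint tip sets.

    Edge-contribution algorithm: an edge of length L below which there are
    ``ca`` aliens and ``cb`` natives separates ``ca*(B-cb) + cb*(A-ca)``
    cross pairs and contributes ``L`` times that count.
    """
    a, b = _check_sets(tree, aliens, natives)
    A, B = len(a), len(b)
    total = 0.0
    counts: dict[dendropy.Node, tuple[int, int]] = {}
    root = tree.dendropy_tree.seed_node
    for node in tree.dendropy_tree.postorder_node_iter():
        if node.is_leaf():
            name = node.taxon.label
            ca, cb = (1 if name in a else 0), (1 if name in b else 0)
        else:
            ca = cb = 0
            for child in node.child_nodes():
                cca, ccb = counts.pop(child)
                ca += cca
                cb += ccb
        counts[node] = (ca, cb)
        if node is not root:
            total += node.edge.length * (ca * (B - cb) + cb * (A - ca))
    return total / (A * B)


def crossgroup_mntd(tree: PhyloTree, aliens, natives) -> float:
    """Mean distance from each alien tip to its nearest native tip."""
    a, b = _check_sets(tree, aliens, natives)
    dmin = native_min_distances(tree, b)
    return float(np.mean([dmin[sp] for sp in a]))


def native_distance_sums(tree: PhyloTree, natives) -> dict[str, float]:
    """For every tip x, the summed patristic distance to a native set B:
    ``S(x) = sum_{b in B} d(x, b)``.

    Because cross-group MPD is linear in the alien set —
    ``MPD(A, B) = mean_{a in A} S(a) / |B|`` — these sums let a null model
    re-draw alien sets at O(|A|) cost per replicate.  Computed with a
    down/up dynamic program in O(n).
    """
    b = set(natives)
    if not b:
        raise ValueError("native set must be non-empty")
    unknown = b - tree.tip_names
    if unknown:
        raise ValueError(f"names not on tree: {sorted(unknown)[:5]}")
    nb_total = len(b)
    down: dict[dendropy.Node, float] = {}
    nb: dict[dendropy.Node, int] = {}
    dtree = tree.dendropy_tree
    for node in dtree.postorder_node_iter():
        if node.is_leaf():
            down[node] = 0.0
            nb[node] = 1 if node.taxon.label in b else 0
        else:
            down[node] = sum(
                down[c] + c.edge.length * nb[c] for c in node.child_nodes()
            )
            nb[node] = sum(nb[c] for c in node.child_nodes())
    up: dict[dendropy.Node, float] = {dtree.seed_node: 0.0}
    for node in dtree.preorder_node_iter():
        for child in node.child_nodes():
            sib = down[node] - down[child] - child.edge.length * nb[child]
            above = nb_total - nb[child]
            up[child] = up[node] + sib + child.edge.length * above
    return {
        leaf.taxon.label: down[leaf] + up[leaf]
        for leaf in dtree.leaf_node_iter()
    }


def native_min_distances(tree: PhyloTree, natives) -> dict[str, float]:
    """For every tip x, the minimum patristic distance to a native set."""
    b = set(natives)
    if not b:
        raise ValueError("native set must be non-empty")
    inf = float("inf")
    down: dict[dendropy.Node, float] = {}
    dtree = tree.dendropy_tree
    for node in dtree.postorder_node_iter():
        if node.is_leaf():
            down[node] = 0.0 if node.taxon.label in b else inf
        else:
            down[node] = min(
                down[c] + c.edge.length for c in node.child_nodes()
            )
    up: dict[dendropy.Node, float] = {dtree.seed_node: inf}
    for node in dtree.preorder_node_iter():
        for child in node.child_nodes():
            best_sib = min(
                (
                    down[c] + c.edge.length
                    for c in node.child_nodes()
                    if c is not child
                ),
                default=inf,
            )
            up[child] = child.edge.length + min(up[node], best_sib)
    out = {}
    for leaf in dtree.leaf_node_iter():
        name = leaf.taxon.label
        out[name] = 0.0 if name in b else up[leaf]
    return out


def patristic_matrix(tree: PhyloTree):
    """Full tip-to-tip patristic distance matrix via dendropy.

    Provided as a reference/oracle utility; the package's statistics never
    materialize this matrix.
    """
    pdm = tree.dendropy_tree.phylogenetic_distance_matrix()
    taxa = sorted(
        (lf.taxon for lf in tree.dendropy_tree.leaf_node_iter()),
        key=lambda t: t.label,
    )
    labels = [t.label for t in taxa]
    n = len(labels)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[i], taxa[j])
            mat[i, j] = mat[j, i] = d
    return labels, mat
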