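"""Compositional-convergence diagnostic for AT-rich lineages.

Lineages that independently drift to extreme AT content can be pulled
together in a tree purely by shared composition. The diagnostic here
removes every alignment column in which a focal taxon carries an A or a T,
rebuilds a bootstrapped tree from the filtered alignment, collapses weakly
supported edges, and asks whether the focal taxon's group placement moves.
A placement that only exists while the AT columns are present is
compositional attraction, not shared ancestry.

Tree building is distance-based (p-distance / JC69 / K2P into neighbor
joining). The placement logic is agnostic to the tree engine, so a
likelihood tree produced elsewhere can be dropped in via
:func:`placement` on any dendropy tree.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np

from .types import MultipleAlignment, TaxonGroups

__all__ = [
    "filter_at_columns", "pairwise_distance", "nj_tree", "bootstrap_tree",
    "collapse_low_support", "placement", "convergence_test",
    "PlacementReport", "ConvergenceTestResult", "DISTANCE_CAP",
    "PLACEMENT_RULE",
]

#: Substitutions/site assigned to pairs whose p-distance saturates the
#: JC69 / K2P transforms (log argument <= 0 or numerically unstable).
DISTANCE_CAP = 5.0

#: p-distance at which the JC69 transform is treated as saturated.
P_SATURATION = 0.749

#: Versioned statement of how a placement label is assigned. Printed in
#: every report so downstream readers know exactly what "placed in X" means.
PLACEMENT_RULE = (
    "smallest-informative-clade-strict-majority/v1: after collapsing "
    "low-support edges, take the smallest side over all non-trivial "
    "bipartitions that contains the focal taxon (the whole taxon set if "
    "the tree is a star); the placement label is the group holding a "
    "strict majority of that side's non-focal members, else 'unresolved'."
)

_MODELS = ("p-distance", "jc69", "k2p")


def filter_at_columns(aln: MultipleAlignment,
                      focal: Iterable[str]) -> MultipleAlignment:
    """Remove every column in which any focal taxon has an A or a T.

    Gaps, N and ambiguity codes in the focal rows retain the column: the
    filter acts only on definite A/T calls. Retained columns are
    unchanged and keep their order, so the operation is idempotent.
    """
    focal = sorted(set(focal))
    if not focal:
        raise ValueError("focal taxon set must be non-empty")
    rows = np.stack([aln.matrix[aln.index(t)] for t in focal])
    is_at = (rows == b"A") | (rows == b"T")
    keep = ~is_at.any(axis=0)
    if not keep.any():
        raise ValueError(
            f"no columns survive AT filtering on focal taxa {focal}")
    return aln.select_columns(keep)


def _encode(aln: MultipleAlignment) -> tuple[np.ndarray, np.ndarray]:
    """(codes, valid): base codes 0..3 and a mask of unambiguous cells."""
    m = aln.matrix
    codes = np.zeros(m.shape, dtype=np.int8)
    valid = np.zeros(m.shape, dtype=bool)
    for i, b in enumerate((b"A", b"C", b"G", b"T")):
        hit = m == b
        codes[hit] = i
        valid |= hit
    return codes, valid


def pairwise_distance(aln: MultipleAlignment,
                      model: str = "jc69") -> np.ndarray:
    """Pairwise evolutionary distances between alignment rows.

    Sites where either sequence has a gap or ambiguity code are excluded
    pairwise. ``model`` is one of ``p-distance`` (raw mismatch fraction),
    ``jc69`` (d = -(3/4) ln(1 - 4p/3)) or ``k2p`` (separate transition /
    transversion rates). Saturated pairs are capped at
    :data:`DISTANCE_CAP` with a warning rather than returning infinity.
    """
    if model not in _MODELS:
        raise ValueError(f"unknown model {model!r}; choose from {_MODELS}")
    if aln.n_taxa < 2:
        raise ValueError("need at least 2 taxa for distances")
    codes, valid = _encode(aln)
    n = aln.n_taxa
    D = np.zeros((n, n), dtype=float)
    # purine<->purine or pyrimidine<->pyrimidine changes are transitions
    is_purine = (codes == 0) | (codes == 2)  # A or G
    saturated = 0
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            n_sites = int(both.sum())
            if n_sites == 0:
                raise ValueError(
                    f"taxa {aln.taxa[i]!r} and {aln.taxa[j]!r} share no "
                    "comparable sites")
            diff = both & (codes[i] != codes[j])
            p = diff.sum() / n_sites
            if model == "p-distance":
                d = p
            elif model == "jc69":
                if p >= P_SATURATION:
                    d = DISTANCE_CAP
                    saturated += 1
                else:
                    d = -0.75 * np.log1p(-4.0 * p / 3.0)
            else:  # k2p
                ts = (diff & (is_purine[i] == is_purine[j])).sum() / n_sites
                tv = p - ts
                a1 = 1.0 - 2.0 * ts - tv
                a2 = 1.0 - 2.0 * tv
                if a1 <= 1e-9 or a2 <= 1e-9:
                    d = DISTANCE_CAP
                    saturated += 1
                else:
                    d = -0.5 * np.log(a1) - 0.25 * np.log(a2)
            D[i, j] = D[j, i] = d
    if saturated:
        warnings.warn(
            f"{saturated} saturated pair(s) capped at {DISTANCE_CAP} "
            "substitutions/site", stacklevel=2)
    return D


def _validate_distance_matrix(D: np.ndarray) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if np.any(np.isnan(D)) or np.any(np.isinf(D)):
        raise ValueError("distance matrix contains NaN or infinite entries")
    if np.any(D < 0):
        raise ValueError("distance matrix contains negative entries")
    if not np.allclose(D, D.T, atol=1e-9):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.abs(np.diag(D)) > 1e-12):
        raise ValueError("distance matrix diagonal must be zero")
    return D


def nj_tree(dist: np.ndarray, taxa: Sequence[str]) -> dendropy.Tree:
    """Neighbor-joining tree from a distance matrix.

    Returns an unrooted dendropy tree (seed node of degree 3). On an
    additive matrix the patristic distances of the result reproduce the
    input exactly, up to floating-point error. Ties in the Q-criterion are
    broken by the first (row-major) minimum, so the result is
    deterministic for a given input ordering.
    """
    D = _validate_distance_matrix(dist).copy()
    taxa = list(taxa)
    if len(taxa) != D.shape[0]:
        raise ValueError("taxa count must match matrix dimension")
    if len(taxa) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    tns = dendropy.TaxonNamespace()
    active: list[dendropy.Node] = []
    for label in taxa:
        node = dendropy.Node(taxon=tns.new_taxon(label))
        active.append(node)
    while len(active) > 3:
        m = len(active)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        i, j = np.unravel_index(int(np.argmin(Q)), Q.shape)
        if i > j:
            i, j = j, i
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = D[i, j] - li
        joined = dendropy.Node()
        joined.add_child(active[i])
        active[i].edge.length = float(li)
        joined.add_child(active[j])
        active[j].edge.length = float(lj)
        dnew = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        D2 = np.empty((m - 1, m - 1), dtype=float)
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = dnew[keep]
        D2[:-1, -1] = dnew[keep]
        D2[-1, -1] = 0.0
        D = D2
        active = [active[k] for k in keep] + [joined]
    hub = dendropy.Node()
    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    lengths = ((d01 + d02 - d12) / 2.0,
               (d01 + d12 - d02) / 2.0,
               (d02 + d12 - d01) / 2.0)
    for node, length in zip(active, lengths):
        hub.add_child(node)
        node.edge.length = float(length)
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=hub)
    tree.is_rooted = False
    return tree


def leaf_labels(tree: dendropy.Tree) -> frozenset[str]:
    return frozenset(leaf.taxon.label for leaf in tree.leaf_node_iter())


def tree_bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial bipartitions as normalized leaf-label sets.

    Each internal edge contributes the side containing the
    lexicographically smallest leaf, so splits compare across trees
    regardless of orientation.
    """
    leaves = leaf_labels(tree)
    ref = min(leaves)
    splits: set[frozenset[str]] = set()
    for node in tree.preorder_internal_node_iter(exclude_seed_node=True):
        below = frozenset(l.taxon.label for l in node.leaf_iter())
        if len(below) < 2 or len(below) > len(leaves) - 2:
            continue
        splits.add(below if ref in below else leaves - below)
    return splits


def _node_support(node: dendropy.Node) -> int | None:
    sup = getattr(node, "support", None)
    if sup is not None:
        return int(sup)
    if node.label is not None:
        try:
            return int(node.label)
        except ValueError:
            return None
    return None


def bootstrap_tree(aln: MultipleAlignment, model: str = "jc69",
                   replicates: int = 100, seed: int = 0) -> dendropy.Tree:
    """NJ tree with bootstrap supports on internal edges.

    The point-estimate tree is built from the full alignment; supports are
    the percentage of column-resampled replicate trees containing each of
    its bipartitions (stored as ``node.support`` and as integer node
    labels). A replicate whose column draw leaves some pair with no
    comparable sites is redrawn.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if aln.n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        point = nj_tree(pairwise_distance(aln, model), aln.taxa)
    rng = np.random.default_rng(seed)
    counts: dict[frozenset[str], int] = {
        split: 0 for split in tree_bipartitions(point)}
    n_cols = aln.n_columns
    for _ in range(replicates):
        for _attempt in range(100):
            idx = rng.integers(0, n_cols, size=n_cols)
            sub = aln.select_columns(idx)
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    D = pairwise_distance(sub, model)
                break
            except ValueError:
                continue
        else:
            raise RuntimeError(
                "could not draw a usable bootstrap replicate in 100 tries")
        rep_splits = tree_bipartitions(nj_tree(D, aln.taxa))
        for split in counts:
            if split in rep_splits:
                counts[split] += 1
    leaves = leaf_labels(point)
    ref = min(leaves)
    for node in point.preorder_internal_node_iter(exclude_seed_node=True):
        below = frozenset(l.taxon.label for l in node.leaf_iter())
        if len(below) < 2 or len(below) > len(leaves) - 2:
            continue
        split = below if ref in below else leaves - below
        support = int(round(100.0 * counts[split] / replicates))
        node.support = support
        node.label = str(support)
    return point


def collapse_low_support(tree: dendropy.Tree,
                         threshold: int = 70) -> dendropy.Tree:
    """Contract every internal edge whose support is below ``threshold``.

    Edges without a support value (including the point tree's root
    artifacts) are kept. The leaf set is unchanged; the result may be
    multifurcating. The input tree is not modified.
    """
    out = tree.clone(depth=1)
    for node in list(out.preorder_internal_node_iter(
            exclude_seed_node=True)):
        sup = _node_support(node)
        if sup is not None and sup < threshold:
            parent = node.parent_node
            for child in list(node.child_nodes()):
                node.remove_child(child)
                parent.add_child(child)
            parent.remove_child(node)
    return out


@dataclass(frozen=True)
class PlacementReport:
    """Where a focal taxon sits in a (collapsed) tree, by group tally."""

    focal: str
    attachment_tally: Mapping[str, int]
    clade_taxa: tuple[str, ...]
    clade_tally: Mapping[str, int]
    label: str
    n_columns: int | None = None
    rule: str = PLACEMENT_RULE

    def to_dict(self) -> dict:
        return {
            "focal": self.focal,
            "attachment_tally": dict(self.attachment_tally),
            "smallest_informative_clade": list(self.clade_taxa),
            "clade_tally": dict(self.clade_tally),
            "placement_label": self.label,
            "n_columns": self.n_columns,
            "rule": self.rule,
        }


def placement(tree: dendropy.Tree, focal: str,
              groups: TaxonGroups,
              n_columns: int | None = None) -> PlacementReport:
    """Assign a group label to the focal taxon's position in the tree.

    The smallest bipartition side containing the focal taxon and at least
    one other taxon is tallied by group; the label is the group with a
    strict majority of the non-focal members, or ``"unresolved"`` on a tie
    or no majority. Assumes low-support edges have already been collapsed
    if a support-aware placement is wanted.
    """
    leaves = leaf_labels(tree)
    if focal not in leaves:
        raise ValueError(f"focal taxon {focal!r} not in tree")
    groups.check_covers(leaves)
    others = sorted(leaves - {focal})
    attachment_tally: dict[str, int] = {}
    for taxon in others:
        g = groups[taxon]
        attachment_tally[g] = attachment_tally.get(g, 0) + 1

    # candidate clades: focal-containing sides of non-trivial bipartitions;
    # a tree with no internal structure left (star) falls back to the whole
    # taxon set, i.e. the placement is read from the attachment tally
    best: frozenset[str] | None = None
    for node in tree.preorder_internal_node_iter(exclude_seed_node=True):
        below = frozenset(l.taxon.label for l in node.leaf_iter())
        if len(below) < 2 or len(below) > len(leaves) - 2:
            continue
        side = below if focal in below else leaves - below
        if best is None or len(side) < len(best) or (
                len(side) == len(best) and sorted(side) < sorted(best)):
            best = side
    if best is None:
        best = frozenset(leaves)
    clade_tally: dict[str, int] = {}
    for taxon in sorted(best - {focal}):
        g = groups[taxon]
        clade_tally[g] = clade_tally.get(g, 0) + 1
    non_focal = sum(clade_tally.values())
    label = "unresolved"
    for g, count in clade_tally.items():
        if 2 * count > non_focal:
            label = g
            break
    return PlacementReport(
        focal=focal,
        attachment_tally=attachment_tally,
        clade_taxa=tuple(sorted(best)),
        clade_tally=clade_tally,
        label=label,
        n_columns=n_columns,
    )


@dataclass(frozen=True)
class ConvergenceTestResult:
    """Paired before/after-filtering placement of a focal taxon."""

    before: PlacementReport
    after: PlacementReport
    moved: bool
    params: Mapping[str, object]
    warnings: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "before": self.before.to_dict(),
            "after": self.after.to_dict(),
            "moved": self.moved,
            "params": dict(self.params),
            "warnings": list(self.warnings),
        }


def convergence_test(aln: MultipleAlignment, focal: str,
                     groups: TaxonGroups, model: str = "jc69",
                     replicates: int = 100, seed: int = 0,
                     support_threshold: int = 70,
                     min_columns: int = 50) -> ConvergenceTestResult:
    """Run the AT-column-removal diagnostic on one focal taxon.

    Builds a bootstrapped tree from the full alignment and from the
    alignment with the focal taxon's A/T columns removed, collapses edges
    with support below ``support_threshold`` in both, and compares the
    focal taxon's placement labels. ``moved`` is True when they differ —
    the signature of a placement driven by composition.
    """
    groups.check_covers(aln.taxa)
    notes: list[str] = []

    def _placed(a: MultipleAlignment, rep_seed: int) -> PlacementReport:
        tree = bootstrap_tree(a, model=model, replicates=replicates,
                              seed=rep_seed)
        collapsed = collapse_low_support(tree, threshold=support_threshold)
        return placement(collapsed, focal, groups, n_columns=a.n_columns)

    before = _placed(aln, seed)
    filtered = filter_at_columns(aln, {focal})
    if filtered.n_columns < min_columns:
        notes.append(
            f"filtered alignment has only {filtered.n_columns} columns "
            f"(minimum advised: {min_columns}); placement may be unstable")
    after = _placed(filtered, seed + 1)
    params = {
        "focal": focal,
        "model": model,
        "replicates": replicates,
        "seed": seed,
        "support_threshold": support_threshold,
        "min_columns": min_columns,
        "columns_before": aln.n_columns,
        "columns_after": filtered.n_columns,
    }
    return ConvergenceTestResult(
        before=before, after=after, moved=before.label != after.label,
        params=params, warnings=tuple(notes))
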