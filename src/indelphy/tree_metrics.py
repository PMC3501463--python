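"""Tree-level statistics for consensus trees with clade supports.

The central quantities:

* **resolution** ``m/(n-2)`` — resolved nontrivial clades over the maximum
  possible for a rooted tree with ``n`` tips (root excluded from ``m``);
* **tree support** — resolution times the mean support of resolved clades, a
  single number in ``[0, 1]`` that is 1 exactly when the consensus is fully
  resolved with unanimous support, and 0 for a star tree;
* **node depth** — mean branch-length path from a node to its descendant
  leaves, a proxy for evolutionary divergence;
* depth-binned support profiles, congruent-clade support ratios between two
  consensus trees, and an OLS fit of support against depth (signal decay).

Trees are treated as rooted throughout; congruence compares clades
(descendant sets), not unrooted bipartitions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import dendropy
import numpy as np
from scipy import stats

from .io_formats import SupportTree, TreeFormatError

logger = logging.getLogger("indelphy")


# ---------------------------------------------------------------------------
# Resolution and tree support
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TreeSupportSummary:
    n: int
    m: int
    resolution: float
    mean_support: float  # NaN when m == 0
    tree_support: float


def resolution(t: SupportTree) -> float:
    """m/(n-2): the fraction of resolvable nontrivial clades that are
    resolved.  1.0 for a fully resolved rooted tree, 0.0 for a star."""
    n = t.n
    if n < 3:
        raise ValueError(f"resolution undefined for n={n} tips (need >= 3)")
    return min(1.0, max(0.0, t.m / (n - 2)))


def tree_support(t: SupportTree) -> TreeSupportSummary:
    """Product of resolution and mean clade support.

    Every resolved clade must carry a support value; a completely unresolved
    tree has tree support 0 by definition (a polytomy contributes nothing).
    """
    res = resolution(t)
    supports = []
    for clade, node in t.clade_leafsets().items():
        s = getattr(node, "support", None)
        if s is None:
            raise ValueError(
                f"resolved clade {sorted(clade)} carries no support value"
            )
        supports.append(s)
    if not supports:
        return TreeSupportSummary(t.n, 0, 0.0, math.nan, 0.0)
    mean = sum(supports) / len(supports)
    return TreeSupportSummary(t.n, t.m, res, mean, res * mean)


# ---------------------------------------------------------------------------
# Node depths
# ---------------------------------------------------------------------------

def node_depths(t: SupportTree) -> dict[frozenset, float]:
    """Depth of every internal node (root included, keyed by its descendant
    leaf-label set): the mean branch-length path to its descendant leaves.
    Tips have depth 0 and are omitted from the map."""
    depths: dict[frozenset, float] = {}
    agg: dict[int, tuple[int, float]] = {}  # node id -> (n_leaves, sum of paths)
    for node in t.tree.postorder_node_iter():
        if node.is_leaf():
            agg[id(node)] = (1, 0.0)
            continue
        total_leaves, total_path = 0, 0.0
        for child in node.child_nodes():
            bl = child.edge.length
            if bl is None:
                raise ValueError("missing branch length; node depths undefined")
            if bl < 0:
                raise ValueError("negative branch length")
            k, s = agg[id(child)]
            total_leaves += k
            total_path += s + bl * k
        agg[id(node)] = (total_leaves, total_path)
        leafset = frozenset(
            lf.taxon.label if lf.taxon else lf.label for lf in node.leaf_iter()
        )
        depths[leafset] = total_path / total_leaves
    return depths


def depth_support_points(t: SupportTree) -> list[tuple[float, float]]:
    """(depth, support) for every resolved non-root clade carrying support."""
    depths = node_depths(t)
    points = []
    for clade, node in t.clade_leafsets().items():
        s = getattr(node, "support", None)
        if s is not None:
            points.append((depths[clade], s))
    return points


# ---------------------------------------------------------------------------
# Depth-binned support profile
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DepthSupportProfile:
    K: int
    edges: tuple[float, ...]        # K+1 edges over [min depth, max depth]
    counts: tuple[int, ...]         # per-bin point counts
    means: tuple[float, ...]        # per-bin mean support; NaN for empty bins

    @property
    def global_mean(self) -> float:
        total = sum(self.counts)
        return sum(c * m for c, m in zip(self.counts, self.means) if c) / total


def bin_depth_support(
    points: Sequence[tuple[float, float]], K: int = 800
) -> DepthSupportProfile:
    """Equal-width binning of supports over the pooled depth range.

    The right edge is inclusive in the last bin.  The count-weighted mean of
    the bin means equals the global mean support (conservation identity).
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if not points:
        raise ValueError("no (depth, support) points")
    d = np.asarray([p[0] for p in points], dtype=float)
    s = np.asarray([p[1] for p in points], dtype=float)
    lo, hi = float(d.min()), float(d.max())
    if lo == hi:
        logger.info("all node depths identical; single occupied bin")
        edges = np.linspace(lo, lo + 1.0, K + 1)
        idx = np.zeros(len(d), dtype=int)
    else:
        edges = np.linspace(lo, hi, K + 1)
        idx = np.minimum(((d - lo) / (hi - lo) * K).astype(int), K - 1)
    counts = np.bincount(idx, minlength=K)
    sums = np.bincount(idx, weights=s, minlength=K)
    means = np.full(K, math.nan)
    occupied = counts > 0
    means[occupied] = sums[occupied] / counts[occupied]
    return DepthSupportProfile(
        K, tuple(edges.tolist()), tuple(counts.tolist()), tuple(means.tolist())
    )


# ---------------------------------------------------------------------------
# Congruent clades
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CongruentPair:
    clade: frozenset
    support_a: Optional[float]
    support_b: Optional[float]

    @property
    def ratio(self) -> float:
        """support_b / support_a (NaN when undefined)."""
        if not self.support_a or self.support_b is None:
            return math.nan
        return self.support_b / self.support_a


def congruent_clades(a: SupportTree, b: SupportTree) -> list[CongruentPair]:
    """Clades with identical descendant-leaf sets on the two trees.

    By convention tree ``a`` is the baseline (e.g. nucleotide-only) and tree
    ``b`` the comparison (e.g. nucleotide+indel), so ratios > 1 favour ``b``.
    """
    tips_a, tips_b = set(a.tip_labels()), set(b.tip_labels())
    if tips_a != tips_b:
        raise ValueError(
            f"tip sets differ: {sorted(tips_a.symmetric_difference(tips_b))}"
        )
    sup_a = a.clade_supports()
    sup_b = b.clade_supports()
    shared = sorted(set(sup_a) & set(sup_b), key=lambda c: (len(c), sorted(c)))
    return [CongruentPair(c, sup_a[c], sup_b[c]) for c in shared]


# ---------------------------------------------------------------------------
# Decay regression
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DecayFit:
    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    r_squared: float


def decay_regression(points: Sequence[tuple[float, float]]) -> DecayFit:
    """OLS of support on depth — the linear decay of signal with divergence."""
    if len(points) < 3:
        raise ValueError("need at least 3 (depth, support) points")
    x = np.asarray([p[0] for p in points], dtype=float)
    y = np.asarray([p[1] for p in points], dtype=float)
    if np.unique(x).size < 2:
        raise ValueError("need at least 2 distinct depths")
    fit = stats.linregress(x, y)
    return DecayFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        slope_se=float(fit.stderr),
        intercept_se=float(fit.intercept_stderr),
        r_squared=float(fit.rvalue) ** 2,
    )


# ---------------------------------------------------------------------------
# Majority-rule consensus
# ---------------------------------------------------------------------------

def build_tree_from_clades(
    taxa: Sequence[str],
    clades: dict[frozenset, tuple[Optional[float], Optional[float]]],
    tip_lengths: Optional[dict[str, Optional[float]]] = None,
) -> SupportTree:
    """Assemble a rooted tree from a pairwise-compatible set of clades.

    ``clades`` maps each nontrivial clade (2 <= size < n) to
    ``(edge_length, support)``; singletons and the full taxon set are
    implicit.  Raises if two clades are incompatible.
    """
    taxa = list(taxa)
    full = frozenset(taxa)
    for c in clades:
        if not (2 <= len(c) < len(taxa)):
            raise ValueError(f"not a nontrivial clade: {sorted(c)}")
        if not c <= full:
            raise ValueError(f"clade {sorted(c)} not within the taxon set")
    ordered = sorted(clades, key=lambda c: (-len(c), sorted(c)))
    for i, c1 in enumerate(ordered):
        for c2 in ordered[i + 1:]:
            if c1 & c2 and not (c1 <= c2 or c2 <= c1):
                raise ValueError(
                    f"incompatible clades {sorted(c1)} / {sorted(c2)}"
                )

    ns = dendropy.TaxonNamespace(sorted(taxa))
    tree = dendropy.Tree(taxon_namespace=ns)
    tree.is_rooted = True
    node_of: dict[frozenset, dendropy.Node] = {full: tree.seed_node}

    def parent_of(c: frozenset) -> dendropy.Node:
        best = full
        for other in ordered:
            if c < other and len(other) < len(best):
                best = other
        return node_of[best]

    for c in ordered:  # descending size: parents exist before children
        node = parent_of(c).new_child()
        length, support = clades[c]
        node.edge.length = length
        node.support = support
        node_of[c] = node

    for label in sorted(taxa):
        singleton = frozenset([label])
        parent = full
        for other in ordered:
            if singleton < other and len(other) < len(parent):
                parent = other
        leaf = node_of[parent].new_child()
        leaf.taxon = ns.get_taxon(label)
        leaf.edge.length = (tip_lengths or {}).get(label)
    return SupportTree(tree)


def majority_consensus(
    trees: Sequence[SupportTree], threshold: float = 0.5
) -> SupportTree:
    """Majority-rule consensus: clades occurring in a fraction of trees
    strictly greater than ``threshold`` are retained, annotated with their
    frequency as support.  Edge lengths are means over the trees containing
    each clade (tips: mean pendant lengths)."""
    if not trees:
        raise ValueError("empty tree list")
    if not (0.5 <= threshold <= 1.0):
        raise ValueError("threshold must lie in [0.5, 1]")
    tips0 = set(trees[0].tip_labels())
    for t in trees[1:]:
        if set(t.tip_labels()) != tips0:
            raise ValueError("trees do not share a tip set")

    counts: dict[frozenset, int] = {}
    lengths: dict[frozenset, list[float]] = {}
    tip_lens: dict[str, list[float]] = {lbl: [] for lbl in tips0}
    n_full = len(tips0)
    for t in trees:
        for clade, node in t.clade_leafsets().items():
            if len(clade) >= n_full:
                continue
            counts[clade] = counts.get(clade, 0) + 1
            if node.edge.length is not None:
                lengths.setdefault(clade, []).append(node.edge.length)
        for leaf in t.tree.leaf_node_iter():
            if leaf.edge.length is not None:
                lbl = leaf.taxon.label if leaf.taxon else leaf.label
                tip_lens[lbl].append(leaf.edge.length)

    B = len(trees)
    retained: dict[frozenset, tuple[Optional[float], Optional[float]]] = {}
    for clade, k in counts.items():
        freq = k / B
        if freq > threshold:
            ls = lengths.get(clade)
            retained[clade] = (sum(ls) / len(ls) if ls else None, freq)
    tip_lengths = {
        lbl: (sum(v) / len(v) if v else None) for lbl, v in tip_lens.items()
    }
    return build_tree_from_clades(sorted(tips0), retained, tip_lengths)
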