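"""Distance-based support surrogate: p-distances, neighbor joining, and a
partitioned nonparametric bootstrap.

This stage supplies clade support values so the treatment comparison
(nucleotide-only vs nucleotide+indel vs masked vs indel-only) runs
end-to-end on synthetic data.  The supports it produces are **bootstrap
proportions** — clade frequencies over neighbor-joining trees built from
resampled columns — not posterior probabilities, and no Bayesian machinery
is involved.  Column resampling is stratified by partition: nucleotide
columns and binary indel characters are resampled independently, each
preserving its own size, so the evidence proportions of the two-partition
design are maintained in every replicate.

Trees are rooted at the lexicographically smallest taxon so that clades are
comparable across replicates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .indel_coding import IndelCharacterMatrix
from .io_formats import MISSING, MultipleAlignment, SupportTree
from .tree_metrics import build_tree_from_clades

logger = logging.getLogger("indelphy")

_NT_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DistanceMatrix:
    taxa: tuple[str, ...]
    values: np.ndarray  # symmetric, zero diagonal, finite

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("distance matrix shape does not match taxa")
        if not np.allclose(v, v.T) or not np.allclose(np.diag(v), 0):
            raise ValueError("distance matrix must be symmetric with zero diagonal")
        if not np.all(np.isfinite(v)) or np.any(v < 0):
            raise ValueError("distances must be finite and non-negative")


def _encode_nucleotides(aln: MultipleAlignment) -> tuple[np.ndarray, np.ndarray]:
    """(codes, valid): codes in 0..3, valid marks unambiguous residues."""
    n, L = aln.n_taxa, aln.length
    codes = np.zeros((n, L), dtype=np.int8)
    valid = np.zeros((n, L), dtype=bool)
    for i, row in enumerate(aln.rows):
        for j, ch in enumerate(row):
            c = _NT_CODE.get(ch)
            if c is not None:
                codes[i, j] = c
                valid[i, j] = True
    return codes, valid


def _encode_indels(m: IndelCharacterMatrix) -> tuple[np.ndarray, np.ndarray]:
    n, C = len(m.taxa), m.n_characters
    codes = np.zeros((n, C), dtype=np.int8)
    valid = np.zeros((n, C), dtype=bool)
    for i, taxon in enumerate(m.taxa):
        for k, char in enumerate(m.characters):
            s = char.states[taxon]
            if s != MISSING:
                codes[i, k] = int(s)
                valid[i, k] = True
    return codes, valid


def pairwise_distance(
    aln: MultipleAlignment, indels: Optional[IndelCharacterMatrix] = None
) -> DistanceMatrix:
    """Combined p-distance.

    Per pair: proportion of mismatches over pairwise comparable positions,
    pooling nucleotide columns (both residues unambiguous) and indel
    characters (both states scored).  The pooling weights each partition by
    its number of compared positions for that pair.
    """
    if aln.n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    if indels is not None and set(indels.taxa) != set(aln.taxa):
        raise ValueError("alignment and indel matrix taxon sets differ")
    codes, valid = _encode_nucleotides(aln)
    if indels is not None and indels.n_characters > 0:
        order = [indels.taxa.index(t) for t in aln.taxa]
        icodes, ivalid = _encode_indels(indels)
        icodes, ivalid = icodes[order], ivalid[order]
        codes = np.concatenate([codes, icodes], axis=1)
        valid = np.concatenate([valid, ivalid], axis=1)
    n = aln.n_taxa
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            comp = int(both.sum())
            if comp == 0:
                raise ValueError(
                    f"no comparable positions between {aln.taxa[i]!r} "
                    f"and {aln.taxa[j]!r}"
                )
            mm = int(((codes[i] != codes[j]) & both).sum())
            d[i, j] = d[j, i] = mm / comp
    return DistanceMatrix(tuple(aln.taxa), d)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

#: internal edges shorter than this are considered zero-length
_ZERO_EDGE = 1e-9


def _nj_clades(
    taxa: tuple[str, ...], d: np.ndarray, collapse_zero: bool = False
) -> tuple[dict[frozenset, float], dict[str, float]]:
    """Neighbor joining returning the rooted clade system.

    The unrooted NJ tree is rooted on the pendant edge of the
    lexicographically smallest taxon (edge split in half).  Returns
    ``(clade -> edge length, tip -> pendant length)``.  Ties in the Q
    criterion break towards the lexicographically smallest (cluster,
    cluster) label pair; negative branch lengths are clamped to zero.

    With ``collapse_zero``, internal edges of (clamped) zero length are
    dropped: NJ always returns a fully resolved topology, so resolution not
    backed by any character shows up as zero-length edges, and counting such
    clades would let the deterministic tie-break manufacture support out of
    no signal.  Bootstrap replicates use this; the public
    :func:`neighbor_joining` keeps full resolution.
    """
    n0 = len(taxa)
    if n0 < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if not np.all(np.isfinite(d)):
        raise ValueError("non-finite distances")

    clusters: list[frozenset] = [frozenset([t]) for t in taxa]
    minlab: list[str] = list(taxa)
    D = d.astype(float).copy()
    clade_len: dict[frozenset, float] = {}
    tip_len: dict[str, float] = {}

    def record(cluster: frozenset, length: float) -> None:
        length = max(0.0, length)
        if len(cluster) == 1:
            tip_len[next(iter(cluster))] = length
        else:
            clade_len[cluster] = length

    while len(clusters) > 3:
        r = len(clusters)
        R = D.sum(axis=1)
        best, best_key = None, None
        for i in range(r):
            for j in range(i + 1, r):
                q = (r - 2) * D[i, j] - R[i] - R[j]
                key = tuple(sorted((minlab[i], minlab[j])))
                if best is None or q < best - 1e-12 or (
                    abs(q - best) <= 1e-12 and key < best_key
                ):
                    best, best_key, bi, bj = q, key, i, j
        vi = 0.5 * D[bi, bj] + (R[bi] - R[bj]) / (2 * (r - 2))
        vj = D[bi, bj] - vi
        if vi < 0 or vj < 0:
            logger.debug("negative NJ branch length clamped to 0")
        record(clusters[bi], vi)
        record(clusters[bj], vj)
        new_cluster = clusters[bi] | clusters[bj]
        new_row = 0.5 * (D[bi] + D[bj] - D[bi, bj])
        keep = [k for k in range(r) if k not in (bi, bj)]
        D2 = np.zeros((r - 1, r - 1))
        D2[: r - 2, : r - 2] = D[np.ix_(keep, keep)]
        D2[-1, : r - 2] = D2[: r - 2, -1] = new_row[keep]
        D = D2
        clusters = [clusters[k] for k in keep] + [new_cluster]
        minlab = [minlab[k] for k in keep] + [min(minlab[bi], minlab[bj])]

    # final three clusters join at the central node
    (a, b, c) = range(3)
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    for k, lk in zip((a, b, c), (la, lb, lc)):
        record(clusters[k], lk)

    # root on the pendant edge of the smallest taxon: every clade flips to
    # the side not containing it; the pendant edge is split in half
    root_taxon = min(taxa)
    full = frozenset(taxa)
    rooted: dict[frozenset, float] = {}
    for clade, length in clade_len.items():
        if collapse_zero and length <= _ZERO_EDGE:
            continue
        side = clade if root_taxon not in clade else full - clade
        if 2 <= len(side) < n0:
            rooted[side] = rooted.get(side, 0.0) + length
    half = tip_len[root_taxon] / 2.0
    tip_len[root_taxon] = half
    opposite = full - frozenset([root_taxon])
    rooted[opposite] = rooted.get(opposite, 0.0) + half
    return rooted, tip_len


def neighbor_joining(d: DistanceMatrix) -> SupportTree:
    """Standard NJ agglomeration, returned as an unannotated rooted tree
    (rooted at the lexicographically smallest taxon)."""
    clades, tips = _nj_clades(d.taxa, d.values)
    return build_tree_from_clades(
        sorted(d.taxa), {c: (l, None) for c, l in clades.items()}, tips
    )


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def bootstrap_support(
    aln: MultipleAlignment,
    indels: Optional[IndelCharacterMatrix] = None,
    B: int = 100,
    seed: int = 0,
) -> SupportTree:
    """Partition-stratified bootstrap over NJ trees.

    ``B`` replicates resample nucleotide columns and indel characters
    independently (each with replacement, preserving partition sizes); the
    majority-rule consensus over replicate trees carries clade frequencies
    as supports.  Fully reproducible under a fixed seed.  Replicates whose
    distance matrix is undefined (a pair with no comparable positions) are
    skipped with a log entry.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    taxa = tuple(aln.taxa)
    codes_nt, valid_nt = _encode_nucleotides(aln)
    has_indels = indels is not None and indels.n_characters > 0
    if has_indels:
        if set(indels.taxa) != set(taxa):
            raise ValueError("alignment and indel matrix taxon sets differ")
        order = [indels.taxa.index(t) for t in taxa]
        codes_in, valid_in = _encode_indels(indels)
        codes_in, valid_in = codes_in[order], valid_in[order]

    n = len(taxa)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    # per-pair per-column mismatch / comparable indicators, computed once
    def _pair_arrays(codes, valid):
        mm = np.empty((len(pairs), codes.shape[1]), dtype=np.int32)
        cp = np.empty_like(mm)
        for p, (i, j) in enumerate(pairs):
            both = valid[i] & valid[j]
            cp[p] = both
            mm[p] = (codes[i] != codes[j]) & both
        return mm, cp

    mm_nt, cp_nt = _pair_arrays(codes_nt, valid_nt)
    if has_indels:
        mm_in, cp_in = _pair_arrays(codes_in, valid_in)

    rng = np.random.default_rng(seed)
    L = aln.length
    C = indels.n_characters if has_indels else 0
    trees_clades: list[dict[frozenset, float]] = []
    trees_tips: list[dict[str, float]] = []
    skipped = 0
    for _ in range(B):
        cols = rng.integers(0, L, size=L)
        mm = mm_nt[:, cols].sum(axis=1)
        cp = cp_nt[:, cols].sum(axis=1)
        if has_indels:
            chars = rng.integers(0, C, size=C)
            mm = mm + mm_in[:, chars].sum(axis=1)
            cp = cp + cp_in[:, chars].sum(axis=1)
        if np.any(cp == 0):
            skipped += 1
            continue
        d = np.zeros((n, n))
        for p, (i, j) in enumerate(pairs):
            d[i, j] = d[j, i] = mm[p] / cp[p]
        clades, tips = _nj_clades(taxa, d, collapse_zero=True)
        trees_clades.append(clades)
        trees_tips.append(tips)

    b_eff = len(trees_clades)
    if skipped:
        logger.warning("bootstrap: %d/%d replicates skipped", skipped, B)
    if b_eff == 0:
        raise ValueError("all bootstrap replicates failed")

    counts: dict[frozenset, int] = {}
    lens: dict[frozenset, float] = {}
    for clades in trees_clades:
        for clade, length in clades.items():
            counts[clade] = counts.get(clade, 0) + 1
            lens[clade] = lens.get(clade, 0.0) + length
    retained = {
        clade: (lens[clade] / k, k / b_eff)
        for clade, k in counts.items()
        if k / b_eff > 0.5
    }
    tip_lengths = {
        t: float(np.mean([tl[t] for tl in trees_tips])) for t in taxa
    }
    return build_tree_from_clades(sorted(taxa), retained, tip_lengths)


def indel_only_distance(indels: IndelCharacterMatrix) -> DistanceMatrix:
    """p-distance over the binary indel matrix alone ('?' skipped)."""
    codes, valid = _encode_indels(indels)
    n = len(indels.taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            comp = int(both.sum())
            if comp == 0:
                raise ValueError(
                    f"no comparable indel characters between "
                    f"{indels.taxa[i]!r} and {indels.taxa[j]!r}"
                )
            d[i, j] = d[j, i] = int(((codes[i] != codes[j]) & both).sum()) / comp
    return DistanceMatrix(tuple(indels.taxa), d)


def bootstrap_support_indels_only(
    indels: IndelCharacterMatrix, B: int = 100, seed: int = 0
) -> SupportTree:
    """Bootstrap over the indel partition alone (characters resampled)."""
    if indels.n_characters == 0:
        raise ValueError("empty indel matrix")
    taxa = tuple(indels.taxa)
    codes, valid = _encode_indels(indels)
    n = len(taxa)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    mm0 = np.empty((len(pairs), codes.shape[1]), dtype=np.int32)
    cp0 = np.empty_like(mm0)
    for p, (i, j) in enumerate(pairs):
        both = valid[i] & valid[j]
        cp0[p] = both
        mm0[p] = (codes[i] != codes[j]) & both
    rng = np.random.default_rng(seed)
    C = indels.n_characters
    trees_clades, trees_tips = [], []
    skipped = 0
    for _ in range(B):
        chars = rng.integers(0, C, size=C)
        mm = mm0[:, chars].sum(axis=1)
        cp = cp0[:, chars].sum(axis=1)
        if np.any(cp == 0):
            skipped += 1
            continue
        d = np.zeros((n, n))
        for p, (i, j) in enumerate(pairs):
            d[i, j] = d[j, i] = mm[p] / cp[p]
        clades, tips = _nj_clades(taxa, d, collapse_zero=True)
        trees_clades.append(clades)
        trees_tips.append(tips)
    if skipped:
        logger.warning("indel-only bootstrap: %d/%d replicates skipped", skipped, B)
    if not trees_clades:
        raise ValueError("all indel-only bootstrap replicates failed")
    b_eff = len(trees_clades)
    counts: dict[frozenset, int] = {}
    lens: dict[frozenset, float] = {}
    for clades in trees_clades:
        for clade, length in clades.items():
            counts[clade] = counts.get(clade, 0) + 1
            lens[clade] = lens.get(clade, 0.0) + length
    retained = {
        clade: (lens[clade] / k, k / b_eff)
        for clade, k in counts.items() if k / b_eff > 0.5
    }
    tip_lengths = {t: float(np.mean([tl[t] for tl in trees_tips])) for t in taxa}
    return build_tree_from_clades(sorted(taxa), retained, tip_lengths)
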