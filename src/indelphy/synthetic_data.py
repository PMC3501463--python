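"""Simulation of ITS-like alignments with known trees and indel events.

The generator emulates the structure of the nuclear ribosomal internal
transcribed spacer region: a highly conserved central block (the 5.8S gene)
flanked by two variable regions (ITS1, ITS2) that are rich in both
substitutions and length mutations.  Trees come from a Yule (pure-birth)
process; sequences evolve down the tree under a single-parameter symmetric
substitution model plus a Poisson indel process whose event lengths follow a
geometric (default, mode 1 with a heavy right tail) or zeta law.

Indel placement uses alignment-of-record bookkeeping: every insertion opens
fresh columns in a global column register, so positional homology in the
emitted "true" alignment is exact by construction — two residues share a
column only if they descend from the same root or inserted residue.  This is
what makes indel-coding recovery exactly testable: every gap block in the
true alignment traces to at least one logged event.
"""

from __future__ import annotations

import json
import logging
import random
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal, Optional

import dendropy
import numpy as np

from .io_formats import GAP, MultipleAlignment, SupportTree, write_fasta

logger = logging.getLogger("indelphy")

REGIONS = ("flank1", "core", "flank2")


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegionProfile:
    """Per-region rate multipliers (flank1, core, flank2) for the two
    mutational processes."""

    substitution: tuple[float, float, float]
    indel: tuple[float, float, float]

    def __post_init__(self) -> None:
        if any(m < 0 for m in self.substitution + self.indel):
            raise ValueError("rate multipliers must be >= 0")


def make_its_profile(
    conserved_multiplier: float,
    variable_multiplier: float,
    indel_flank_multiplier: float = 1.0,
    indel_core_multiplier: float = 0.0,
) -> RegionProfile:
    """ITS-style profile: slow core, fast flanks; indels confined to the
    flanks by default (core indel multiplier 0)."""
    if conserved_multiplier > variable_multiplier:
        raise ValueError("conserved multiplier must not exceed variable multiplier")
    return RegionProfile(
        substitution=(variable_multiplier, conserved_multiplier, variable_multiplier),
        indel=(indel_flank_multiplier, indel_core_multiplier, indel_flank_multiplier),
    )


@dataclass(frozen=True)
class SimParams:
    """Simulation settings.

    Rates are per site per unit branch length (branch lengths in expected
    Yule time units); ``indel_rate`` counts events.  ``length_distribution``
    is ``("geometric", p)`` or ``("zeta", a)`` over integers >= 1; the
    default geometric(0.5) has mode 1 and a heavy right tail, the shape
    empirical indel-length spectra show.  Default region lengths (80, 100,
    80) are a desk-scale ITS1 / 5.8S / ITS2.
    """

    n_tips: int = 12
    birth_rate: float = 1.0
    substitution_rate: float = 1.0
    indel_rate: float = 0.01
    insertion_fraction: float = 0.5
    length_distribution: tuple[str, float] = ("geometric", 0.5)
    region_profile: RegionProfile = field(
        default_factory=lambda: make_its_profile(0.05, 1.0)
    )
    root_lengths: tuple[int, int, int] = (80, 100, 80)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tips < 3:
            raise ValueError("n_tips must be >= 3")
        for r in (self.birth_rate, self.substitution_rate, self.indel_rate):
            if r < 0:
                raise ValueError("rates must be >= 0")
        if not (0.0 <= self.insertion_fraction <= 1.0):
            raise ValueError("insertion_fraction must lie in [0, 1]")
        if any(l < 1 for l in self.root_lengths):
            raise ValueError("region lengths must be >= 1")
        kind, _ = self.length_distribution
        if kind not in ("geometric", "zeta"):
            raise ValueError("length_distribution must be geometric or zeta")

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=2, sort_keys=True)


def saturated_flank_params(n_tips: int = 12, seed: int = 0) -> SimParams:
    """Study conditions for the treatment comparison.

    Flanks accumulate ~2 substitutions per site per unit time, so pairwise
    flank distances saturate at deep divergences while recent splits remain
    informative — the depth-wise signal decay of fast spacer regions.  The
    core is nearly invariant (like 5.8S).  Indel events are sparse relative
    to substitutions (roughly 40x fewer mutation events), yet yield a
    character set about half the size of the variable nucleotide site set,
    the ratio real spacer alignments show.
    """
    return SimParams(
        n_tips=n_tips,
        birth_rate=1.0,
        substitution_rate=1.0,
        indel_rate=0.08,
        insertion_fraction=0.5,
        region_profile=make_its_profile(0.01, 2.0),
        root_lengths=(80, 100, 80),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Events and truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrueIndelEvent:
    branch: str                      # label of the child node of the edge
    type: Literal["insertion", "deletion"]
    start: int                       # true-alignment columns, [start, end)
    end: int
    length: int                      # residues inserted / deleted

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SyntheticTruth:
    tree: dendropy.Tree              # with branch lengths, leaf labels T01..
    alignment: MultipleAlignment     # the true alignment (exact homology)
    events: tuple[TrueIndelEvent, ...]
    unaligned: dict[str, str]        # taxon -> gap-free sequence
    region_of_column: tuple[str, ...]
    params: SimParams

    def support_tree(self) -> SupportTree:
        return SupportTree(self.tree)


# ---------------------------------------------------------------------------
# Yule trees
# ---------------------------------------------------------------------------

def simulate_yule_tree(n_tips: int, birth_rate: float, seed: int) -> dendropy.Tree:
    """Pure-birth (Yule) tree: while ``k`` lineages exist the next
    speciation arrives after Exponential(k x birth_rate) time and splits a
    uniformly chosen lineage; after the n-th lineage appears one further
    exponential interval runs to the present, so pendant branches are
    never zero.  The tree is ultrametric.  Leaves are relabelled
    ``T1..Tn`` and internal nodes ``N1..`` (preorder) so every branch has a
    stable identifier."""
    if n_tips < 3:
        raise ValueError("n_tips must be >= 3")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be > 0")
    rng = random.Random(seed)
    ns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=ns)
    tree.is_rooted = True
    root = tree.seed_node
    active = [root.new_child(), root.new_child()]
    birth = {id(nd): 0.0 for nd in active}
    t, k = 0.0, 2
    while k < n_tips:
        t += rng.expovariate(k * birth_rate)
        idx = rng.randrange(k)
        node = active[idx]
        node.edge.length = t - birth[id(node)]
        a, b = node.new_child(), node.new_child()
        birth[id(a)] = birth[id(b)] = t
        active[idx] = a
        active.append(b)
        k += 1
    t += rng.expovariate(k * birth_rate)
    for node in active:
        node.edge.length = t - birth[id(node)]
    width = len(str(n_tips))
    leaf_i = node_i = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            leaf_i += 1
            node.taxon = ns.new_taxon(f"T{leaf_i:0{width}d}")
            node.label = node.taxon.label
        else:
            node_i += 1
            node.label = f"N{node_i}"
    return tree


# ---------------------------------------------------------------------------
# Sequence evolution
# ---------------------------------------------------------------------------

def _draw_length(kind: str, param: float, rng: np.random.Generator) -> int:
    if kind == "geometric":
        return int(rng.geometric(param))
    return int(rng.zipf(param))


def _jc_substitute(
    bases: np.ndarray, expected: float, rng: np.random.Generator
) -> np.ndarray:
    """Symmetric single-parameter model: each site changes with probability
    3/4 (1 - exp(-4/3 mu t)), to a uniform different base."""
    if expected <= 0 or bases.size == 0:
        return bases
    p_change = 0.75 * (1.0 - np.exp(-4.0 / 3.0 * expected))
    hit = rng.random(bases.size) < p_change
    if hit.any():
        bases = bases.copy()
        shift = rng.integers(1, 4, size=int(hit.sum()))
        bases[hit] = (bases[hit] + shift) % 4
    return bases


def evolve_sequences(tree: dendropy.Tree, p: SimParams) -> SyntheticTruth:
    """Evolve sequences down ``tree`` and return the exact truth record.

    Along each branch, substitutions are applied first to the inherited
    residues, then indel events are drawn per region from a Poisson process
    with mean ``indel_rate x multiplier x region length x branch length``.
    Deletions remove present residues (truncated at region boundaries);
    insertions open fresh columns in the alignment of record.
    """
    rng = np.random.default_rng(p.seed)
    sub_mult = dict(zip(REGIONS, p.region_profile.substitution))
    ind_mult = dict(zip(REGIONS, p.region_profile.indel))
    kind, lparam = p.length_distribution

    # global column register
    next_id = 0
    column_order: list[int] = []
    region_of: dict[int, str] = {}
    for region, rlen in zip(REGIONS, p.root_lengths):
        for _ in range(rlen):
            column_order.append(next_id)
            region_of[next_id] = region
            next_id += 1

    root_bases = rng.integers(0, 4, size=len(column_order))
    root_seq: dict[int, int] = {
        cid: int(b) for cid, b in zip(column_order, root_bases)
    }

    order_index_dirty = [True]  # position lookup cache flag

    def _positions() -> dict[int, int]:
        return {cid: k for k, cid in enumerate(column_order)}

    events: list[TrueIndelEvent] = []
    event_cols: list[tuple[int, list[int]]] = []  # parallel: event idx -> col ids
    seqs: dict[str, dict[int, int]] = {}

    def _evolve_branch(
        parent_seq: dict[int, int], node: dendropy.Node
    ) -> dict[int, int]:
        nonlocal next_id
        bl = node.edge.length or 0.0
        seq = dict(parent_seq)

        # substitutions, per region
        if bl > 0 and p.substitution_rate > 0:
            by_region: dict[str, list[int]] = {r: [] for r in REGIONS}
            for cid in seq:
                by_region[region_of[cid]].append(cid)
            for region, cids in by_region.items():
                mu = p.substitution_rate * sub_mult[region] * bl
                if mu <= 0 or not cids:
                    continue
                arr = np.fromiter((seq[c] for c in cids), dtype=np.int64)
                arr = _jc_substitute(arr, mu, rng)
                for c, b in zip(cids, arr.tolist()):
                    seq[c] = b

        # indels, per region
        if bl > 0 and p.indel_rate > 0:
            pos = _positions()
            for region in REGIONS:
                present = sorted(
                    (c for c in seq if region_of[c] == region),
                    key=pos.__getitem__,
                )
                lam = p.indel_rate * ind_mult[region] * len(present) * bl
                if lam <= 0:
                    continue
                n_events = int(rng.poisson(lam))
                for _ in range(n_events):
                    if not present:
                        raise ValueError(
                            f"region {region} emptied on branch "
                            f"{node.label}; lower the indel rate"
                        )
                    length = _draw_length(kind, lparam, rng)
                    if rng.random() < p.insertion_fraction:
                        # insertion: new columns after a uniform position
                        at = int(rng.integers(0, len(present) + 1))
                        anchor = (
                            pos[present[at - 1]] if at > 0
                            else pos[present[0]] - 1
                        )
                        new_ids = list(range(next_id, next_id + length))
                        next_id += length
                        for k, cid in enumerate(new_ids):
                            region_of[cid] = region
                            seq[cid] = int(rng.integers(0, 4))
                        column_order[anchor + 1 : anchor + 1] = new_ids
                        pos = _positions()
                        present = sorted(
                            (c for c in seq if region_of[c] == region),
                            key=pos.__getitem__,
                        )
                        events.append(TrueIndelEvent(
                            node.label, "insertion", -1, -1, length))
                        event_cols.append((len(events) - 1, new_ids))
                    else:
                        # deletion: contiguous present residues, truncated
                        # at the region boundary
                        at = int(rng.integers(0, len(present)))
                        victims = present[at : at + length]
                        for c in victims:
                            del seq[c]
                        present = present[:at] + present[at + len(victims):]
                        events.append(TrueIndelEvent(
                            node.label, "deletion", -1, -1, len(victims)))
                        event_cols.append((len(events) - 1, victims))
                    if not present:
                        raise ValueError(
                            f"region {region} emptied on branch "
                            f"{node.label}; lower the indel rate"
                        )
        return seq

    # DFS down the tree
    node_seq: dict[int, dict[int, int]] = {id(tree.seed_node): root_seq}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent = node_seq[id(node.parent_node)]
        node_seq[id(node)] = _evolve_branch(parent, node)
    for leaf in tree.leaf_node_iter():
        seqs[leaf.taxon.label] = node_seq[id(leaf)]

    # assemble the true alignment
    pos = _positions()
    taxa = sorted(seqs)
    rows = []
    for t in taxa:
        s = seqs[t]
        row = [GAP] * len(column_order)
        for cid, b in s.items():
            row[pos[cid]] = "ACGT"[b]
        rows.append("".join(row))
    alignment = MultipleAlignment(tuple(taxa), tuple(rows))

    # finalise event coordinates in true-alignment space
    final_events: list[TrueIndelEvent] = []
    for (idx, cols) in event_cols:
        ev = events[idx]
        positions = [pos[c] for c in cols]
        final_events.append(TrueIndelEvent(
            ev.branch, ev.type, min(positions), max(positions) + 1, ev.length
        ))

    unaligned = {
        t: row.replace(GAP, "") for t, row in zip(taxa, rows)
    }
    region_cols = tuple(region_of[cid] for cid in column_order)
    return SyntheticTruth(
        tree=tree,
        alignment=alignment,
        events=tuple(final_events),
        unaligned=unaligned,
        region_of_column=region_cols,
        params=p,
    )


def simulate_dataset(p: SimParams) -> SyntheticTruth:
    """Convenience: Yule tree + sequence evolution, all randomness from
    ``p.seed`` (tree and mutation streams use derived sub-seeds)."""
    ss = np.random.SeedSequence(p.seed)
    tree_seed, evo_seed = (int(s) for s in ss.generate_state(2) >> 1)
    tree = simulate_yule_tree(p.n_tips, p.birth_rate, tree_seed)
    p_evo = SimParams(**{**asdict(p), "seed": evo_seed,
                         "region_profile": p.region_profile})
    return evolve_sequences(tree, p_evo)


def strip_gaps(truth: SyntheticTruth) -> dict[str, str]:
    """Per-taxon gap-free sequences (identical to ``truth.unaligned``)."""
    return {
        t: row.replace(GAP, "") for t, row in truth.alignment.iter_pairs()
    }


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_truth(truth: SyntheticTruth, outdir: str | Path) -> None:
    """Write the full truth record: true alignment (FASTA), unaligned FASTA,
    true tree (Newick), event log (TSV) and a JSON manifest of SimParams."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(truth.alignment, outdir / "true_alignment.fasta")
    with open(outdir / "unaligned.fasta", "w") as fh:
        for t in sorted(truth.unaligned):
            fh.write(f">{t}\n{truth.unaligned[t]}\n")
    truth.tree.write(path=str(outdir / "true_tree.nwk"), schema="newick")
    with open(outdir / "events.tsv", "w") as fh:
        fh.write("branch\ttype\tstart\tend\tlength\n")
        for ev in truth.events:
            fh.write(f"{ev.branch}\t{ev.type}\t{ev.start}\t{ev.end}\t{ev.length}\n")
    (outdir / "params.json").write_text(truth.params.to_json())
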