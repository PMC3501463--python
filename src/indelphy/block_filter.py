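"""Block selection: exclusion of ambiguously aligned, gap-rich regions.

Implements a Gblocks-style block filter.  Columns are first classed by gap
content and by the frequency of their most common residue; blocks are then
selected in four steps:

1. reject stretches of more than ``max_contiguous_nonconserved`` contiguous
   nonconserved-or-gap-excluded columns;
2. trim each surviving segment inward to the nearest highly conserved column;
3. reject every gap-excluded column plus any nonconserved column contiguous
   with one;
4. drop surviving blocks shorter than ``min_block_length``.

Byte-compatibility with any particular filtering program is not a goal; this
four-step procedure is the normative definition.  The defaults mirror the
"less stringent" setting commonly used on ITS alignments: up to 15 contiguous
nonconserved positions, minimum block length 5, and up to half of the
sequences gapped at a retained site.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional

from .io_formats import GAP, MultipleAlignment

logger = logging.getLogger("indelphy")

ColumnStatus = Literal["gap_excluded", "nonconserved", "conserved", "highly_conserved"]

#: symbols that do not count as residues when scoring conservation
_NON_RESIDUE = frozenset("-?N")


@dataclass(frozen=True)
class BlockParams:
    """Filter thresholds.

    ``min_conserved_fraction=None`` means "strictly more than half the
    sequences" (the classical default: floor(n/2)+1 sequences).  The
    conserved-fraction denominator includes gapped rows: a gap is not a
    residue but counts in the total.
    """

    min_conserved_fraction: Optional[float] = None
    min_flank_fraction: float = 0.85
    max_contiguous_nonconserved: int = 15
    min_block_length: int = 5
    max_gap_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.min_conserved_fraction is not None:
            if not (0 < self.min_conserved_fraction <= self.min_flank_fraction <= 1):
                raise ValueError("need 0 < min_conserved_fraction <= min_flank_fraction <= 1")
        if self.max_contiguous_nonconserved < 1:
            raise ValueError("max_contiguous_nonconserved must be >= 1")
        if self.min_block_length < 1:
            raise ValueError("min_block_length must be >= 1")
        if not (0 <= self.max_gap_fraction <= 1):
            raise ValueError("max_gap_fraction must lie in [0, 1]")

    def conserved_threshold(self, n_taxa: int) -> float:
        if self.min_conserved_fraction is not None:
            return self.min_conserved_fraction
        return (n_taxa // 2 + 1) / n_taxa


@dataclass(frozen=True)
class BlockMask:
    """Retained columns as both a flat sorted list and contiguous blocks."""

    retained: tuple[int, ...]
    blocks: tuple[tuple[int, int], ...]

    @classmethod
    def from_columns(cls, cols: list[int]) -> "BlockMask":
        cols = sorted(cols)
        blocks: list[tuple[int, int]] = []
        i = 0
        while i < len(cols):
            j = i
            while j + 1 < len(cols) and cols[j + 1] == cols[j] + 1:
                j += 1
            blocks.append((cols[i], cols[j] + 1))
            i = j + 1
        return cls(tuple(cols), tuple(blocks))

    @property
    def n_retained(self) -> int:
        return len(self.retained)


def classify_columns(aln: MultipleAlignment, p: BlockParams) -> list[ColumnStatus]:
    """Per-column status by gap fraction and most-frequent-residue fraction."""
    n = aln.n_taxa
    t_cons = p.conserved_threshold(n)
    out: list[ColumnStatus] = []
    for j in range(aln.length):
        col = aln.column(j)
        gap_frac = sum(ch == GAP for ch in col) / n
        if gap_frac > p.max_gap_fraction:
            out.append("gap_excluded")
            continue
        residue_counts: dict[str, int] = {}
        for ch in col:
            if ch not in _NON_RESIDUE:
                residue_counts[ch] = residue_counts.get(ch, 0) + 1
        f = max(residue_counts.values(), default=0) / n
        if f < t_cons:
            out.append("nonconserved")
        elif f < p.min_flank_fraction:
            out.append("conserved")
        else:
            out.append("highly_conserved")
    return out


def select_blocks(aln: MultipleAlignment, p: BlockParams) -> BlockMask:
    """Apply the four selection steps and return the mask of retained columns."""
    L = aln.length
    status = classify_columns(aln, p)
    alive = [True] * L

    # step 1: long stretches of nonconserved / gap-excluded columns
    j = 0
    while j < L:
        if status[j] in ("nonconserved", "gap_excluded"):
            k = j
            while k < L and status[k] in ("nonconserved", "gap_excluded"):
                k += 1
            if k - j > p.max_contiguous_nonconserved:
                for i in range(j, k):
                    alive[i] = False
            j = k
        else:
            j += 1

    # step 2: trim each surviving segment inward to a highly conserved column
    j = 0
    while j < L:
        if alive[j]:
            k = j
            while k < L and alive[k]:
                k += 1
            lo, hi = j, k - 1
            while lo <= hi and status[lo] != "highly_conserved":
                alive[lo] = False
                lo += 1
            while hi >= lo and status[hi] != "highly_conserved":
                alive[hi] = False
                hi -= 1
            j = k
        else:
            j += 1

    # step 3: gap-excluded columns and nonconserved columns contiguous with one
    gappy = [alive[i] and status[i] == "gap_excluded" for i in range(L)]
    for i in range(L):
        if gappy[i]:
            alive[i] = False
            k = i - 1
            while k >= 0 and alive[k] and status[k] == "nonconserved":
                alive[k] = False
                k -= 1
            k = i + 1
            while k < L and alive[k] and status[k] == "nonconserved":
                alive[k] = False
                k += 1

    # step 4: drop short blocks
    cols = [i for i in range(L) if alive[i]]
    mask = BlockMask.from_columns(cols)
    kept = [b for b in mask.blocks if b[1] - b[0] >= p.min_block_length]
    final_cols = [i for (s, e) in kept for i in range(s, e)]
    if not final_cols:
        logger.info("block filter retained no columns")
    return BlockMask.from_columns(final_cols)


def apply_mask(aln: MultipleAlignment, mask: BlockMask) -> MultipleAlignment:
    """Column-subset alignment; may be 0-column and may contain all-gap rows
    (downstream stages must tolerate both; a notice is logged)."""
    out = aln.take_columns(list(mask.retained))
    if out.length == 0:
        logger.warning("masked alignment has zero columns")
    else:
        allgap = [t for t, r in out.iter_pairs() if set(r) <= {GAP}]
        if allgap:
            logger.warning("masked alignment has all-gap rows: %s", allgap)
    return out


def write_mask_tsv(mask: BlockMask, path: str | Path) -> None:
    """Two-column TSV of [start, end) block ranges plus a flat column list."""
    with open(path, "w") as fh:
        fh.write("block_start\tblock_end\n")
        for s, e in mask.blocks:
            fh.write(f"{s}\t{e}\n")
        fh.write("# retained\t" + ",".join(map(str, mask.retained)) + "\n")
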