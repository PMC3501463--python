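"""Shared fixtures and independent oracles.

The oracles here are deliberately independent re-derivations (regex scans,
exhaustive enumeration, closed-form algebra) of the quantities the package
computes, so agreement is meaningful.
"""

from __future__ import annotations

import itertools
import re

import numpy as np
import pytest

from indelphy.io_formats import MultipleAlignment


# ---------------------------------------------------------------------------
# Random alignments
# ---------------------------------------------------------------------------

def random_alignment(
    rng: np.random.Generator,
    max_taxa: int = 8,
    max_cols: int = 40,
    gap_prob: float = 0.25,
) -> MultipleAlignment:
    """Random gapped alignment; rows are never all-gap."""
    n = int(rng.integers(2, max_taxa + 1))
    L = int(rng.integers(2, max_cols + 1))
    rows = []
    for i in range(n):
        while True:
            row = "".join(
                "-" if rng.random() < gap_prob else "ACGT"[rng.integers(0, 4)]
                for _ in range(L)
            )
            if set(row) != {"-"}:
                break
        rows.append(row)
    taxa = tuple(f"t{i}" for i in range(n))
    return MultipleAlignment(taxa, tuple(rows))


# ---------------------------------------------------------------------------
# Brute-force simple indel coding (regex-based literal rule application)
# ---------------------------------------------------------------------------

def oracle_indel_coding(aln: MultipleAlignment):
    """Independent enumerator: regex-extract every maximal gap run, take each
    distinct internal (start, end) as a character, and score states by a
    literal reading of the three coding rules."""
    L = aln.length

    def runs(row):
        return [(m.start(), m.end()) for m in re.finditer(r"-+", row)]

    def is_terminal(s, e):
        return s == 0 or e == L

    chars = sorted({
        (s, e)
        for row in aln.rows
        for (s, e) in runs(row)
        if not is_terminal(s, e)
    })
    states = {}
    for taxon, row in aln.iter_pairs():
        rr = runs(row)
        for (s, e) in chars:
            if (s, e) in rr and not is_terminal(s, e):
                st = 1
            elif any(
                is_terminal(ts, te) and ts < e and s < te for (ts, te) in rr
            ):
                st = "?"  # overlaps a leading/trailing gap: missing data
            elif any(
                (rs, re_) != (s, e) and rs <= s and e <= re_
                for (rs, re_) in rr
                if not is_terminal(rs, re_)
            ):
                st = "?"  # falls within the range of a longer indel
            else:
                st = 0
            states[(taxon, (s, e))] = st
    return chars, states


# ---------------------------------------------------------------------------
# Exhaustive rooted-binary-tree enumeration (newick strings)
# ---------------------------------------------------------------------------

def all_rooted_binary_newicks(labels: tuple[str, ...]):
    """Every rooted binary topology over the labels, as newick strings with
    unit branch lengths."""
    def build(lbls):
        if len(lbls) == 1:
            yield f"{lbls[0]}:1"
            return
        first, rest = lbls[0], lbls[1:]
        # split rest into the set joined with `first` vs the sibling side
        for k in range(0, len(rest)):
            for left_rest in itertools.combinations(rest, k):
                right = tuple(l for l in rest if l not in left_rest)
                if not right:
                    continue
                for lt in build((first,) + left_rest):
                    for rt in build(right):
                        yield f"({lt},{rt}):1"
    for t in build(tuple(labels)):
        yield t[: t.rfind(":")] + ";"


def newick_clades(newick: str) -> set[frozenset]:
    """Nontrivial clades of a rooted newick string, by bracket matching —
    independent of any tree library."""
    s = newick.rstrip(";")
    clades = set()
    stack: list[list[str]] = []
    label = ""
    all_labels = set(re.findall(r"[A-Za-z]\w*", re.sub(r":\d+(\.\d+)?", "", s)))
    for ch in s:
        if ch == "(":
            stack.append([])
        elif ch in ",)":
            if label:
                name = label.split(":")[0]
                if name:
                    for grp in stack:
                        grp.append(name)
                label = ""
            if ch == ")":
                grp = stack.pop()
                c = frozenset(grp)
                if 2 <= len(c) < len(all_labels):
                    clades.add(c)
                for g in stack:
                    g.extend(grp)
        else:
            label += ch
    return clades


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
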