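"""Alignment and tree I/O for gap-rich rDNA (ITS-style) analyses.

Alignments are nucleotide matrices over the alphabet ``{A,C,G,T,N,?,-}``;
IUPAC ambiguity codes are accepted on read and collapsed to ``N``.  Trees are
rooted, with clade support values in ``[0, 1]`` attached to internal nodes.

Column coordinates are 0-based, half-open ``[start, end)`` throughout the
package.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import dendropy
from Bio import AlignIO, SeqIO

logger = logging.getLogger("indelphy")

GAP = "-"
MISSING = "?"
RESIDUES = frozenset("ACGT")
ALPHABET = frozenset("ACGTN?-")
#: IUPAC nucleotide ambiguity codes collapsed to N on read.
IUPAC_AMBIGUOUS = frozenset("RYSWKMBDHV")


class AlignmentFormatError(ValueError):
    """Raised when an input alignment violates the matrix contract."""


class TreeFormatError(ValueError):
    """Raised when a support tree cannot be parsed or validated."""


# ---------------------------------------------------------------------------
# MultipleAlignment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MultipleAlignment:
    """A taxa-by-columns nucleotide matrix.

    Parameters
    ----------
    taxa:
        Ordered, unique, non-empty taxon labels.
    rows:
        One symbol string per taxon, all of identical length, over
        ``{A,C,G,T,N,?,-}`` (stored upper-case).
    """

    taxa: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.taxa) < 2:
            raise AlignmentFormatError("alignment needs at least 2 taxa")
        if len(self.taxa) != len(self.rows):
            raise AlignmentFormatError("taxa/rows length mismatch")
        dupes = [t for t, c in Counter(self.taxa).items() if c > 1]
        if dupes:
            raise AlignmentFormatError(f"duplicate taxon labels: {sorted(dupes)}")
        if any(not t for t in self.taxa):
            raise AlignmentFormatError("empty taxon label")
        length = len(self.rows[0])
        for taxon, row in zip(self.taxa, self.rows):
            if len(row) != length:
                raise AlignmentFormatError(
                    f"ragged alignment: row for {taxon!r} has length "
                    f"{len(row)}, expected {length}"
                )
            bad = set(row) - ALPHABET
            if bad:
                raise AlignmentFormatError(
                    f"illegal symbols {sorted(bad)} in row for {taxon!r}"
                )

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "MultipleAlignment":
        pairs = list(pairs)
        return cls(
            taxa=tuple(t for t, _ in pairs),
            rows=tuple(_sanitize_row(r, t) for t, r in pairs),
        )

    @property
    def length(self) -> int:
        return len(self.rows[0])

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def row(self, taxon: str) -> str:
        return self.rows[self.taxa.index(taxon)]

    def column(self, j: int) -> tuple[str, ...]:
        return tuple(r[j] for r in self.rows)

    def take_columns(self, cols: Sequence[int]) -> "MultipleAlignment":
        """Column-subset alignment preserving taxon order (may be 0-column)."""
        for j in cols:
            if not 0 <= j < self.length:
                raise IndexError(f"column {j} out of range 0..{self.length - 1}")
        rows = tuple("".join(r[j] for j in cols) for r in self.rows)
        return _unchecked_alignment(self.taxa, rows)

    def iter_pairs(self) -> Iterable[tuple[str, str]]:
        return zip(self.taxa, self.rows)


def _unchecked_alignment(taxa: tuple[str, ...], rows: tuple[str, ...]) -> MultipleAlignment:
    """Construct without invariant checks (internal: masked alignments may be
    0-column or contain all-gap rows, which downstream stages must tolerate)."""
    obj = object.__new__(MultipleAlignment)
    object.__setattr__(obj, "taxa", taxa)
    object.__setattr__(obj, "rows", rows)
    return obj


def _sanitize_row(row: str, taxon: str) -> str:
    out = []
    warned: set[str] = set()
    for ch in row.upper():
        if ch in ALPHABET:
            out.append(ch)
        elif ch == "U":
            out.append("T")
        elif ch == ".":
            out.append(GAP)
        elif ch in IUPAC_AMBIGUOUS:
            if ch not in warned:
                logger.warning(
                    "ambiguity code %r in %s mapped to N", ch, taxon
                )
                warned.add(ch)
            out.append("N")
        else:
            raise AlignmentFormatError(
                f"illegal symbol {ch!r} in row for {taxon!r}"
            )
    return "".join(out)


# ---------------------------------------------------------------------------
# Alignment readers / writers
# ---------------------------------------------------------------------------

_FORMAT_MAP = {"fasta": "fasta", "nexus": "nexus", "phylip": "phylip-relaxed"}


def read_alignment(path: str | Path, format: str = "fasta") -> MultipleAlignment:
    """Read an alignment file into a :class:`MultipleAlignment`.

    Supported formats: ``fasta`` (relaxed, wrapped or unwrapped), ``nexus``
    (DATA/CHARACTERS blocks) and ``phylip``.  Ragged rows and duplicate labels
    raise :class:`AlignmentFormatError` naming the offending taxa.
    """
    if format not in _FORMAT_MAP:
        raise ValueError(f"unknown alignment format {format!r}")
    path = Path(path)
    if format == "fasta":
        # SeqIO tolerates ragged records; length check happens in the
        # constructor so the error can name the taxon.
        records = list(SeqIO.parse(str(path), "fasta"))
    else:
        try:
            records = list(AlignIO.read(str(path), _FORMAT_MAP[format]))
        except ValueError as exc:
            raise AlignmentFormatError(f"cannot parse {path} as {format}: {exc}") from exc
    if not records:
        raise AlignmentFormatError(f"no sequences found in {path}")
    return MultipleAlignment.from_pairs((r.id, str(r.seq)) for r in records)


def sanitize_label(label: str) -> str:
    """Spaces become underscores on write; the mapping is logged so it can be
    reversed by the caller if needed."""
    clean = label.replace(" ", "_")
    if clean != label:
        logger.info("taxon label %r written as %r", label, clean)
    return clean


def write_fasta(aln: MultipleAlignment, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for taxon, row in aln.iter_pairs():
            fh.write(f">{sanitize_label(taxon)}\n")
            for i in range(0, len(row), width):
                fh.write(row[i : i + width] + "\n")


def write_nexus(aln: MultipleAlignment, path: str | Path) -> None:
    """Write a plain DNA NEXUS DATA block (deterministic output)."""
    with open(path, "w") as fh:
        fh.write("#NEXUS\n\nBEGIN DATA;\n")
        fh.write(f"    DIMENSIONS NTAX={aln.n_taxa} NCHAR={aln.length};\n")
        fh.write('    FORMAT DATATYPE=DNA MISSING=? GAP=-;\n    MATRIX\n')
        pad = max(len(sanitize_label(t)) for t in aln.taxa) + 2
        for taxon, row in aln.iter_pairs():
            fh.write(f"    {sanitize_label(taxon):<{pad}}{row}\n")
        fh.write("    ;\nEND;\n")


def write_alignment(aln: MultipleAlignment, path: str | Path, format: str = "fasta") -> None:
    if format == "fasta":
        write_fasta(aln, path)
    elif format == "nexus":
        write_nexus(aln, path)
    else:
        raise ValueError(f"unsupported output format {format!r}")


# ---------------------------------------------------------------------------
# Terminal trimming
# ---------------------------------------------------------------------------

def trim_terminal_overhangs(
    aln: MultipleAlignment, start_motif: str = "CATTA"
) -> MultipleAlignment:
    """Trim ragged terminal overhangs so rows start at a conserved motif.

    The motif (e.g. the CATTA at the 3' end of 18S, immediately upstream of
    ITS1) is located on each row's ungapped sequence and mapped back to the
    alignment column of its first base.  Columns before the modal first-match
    column are removed.  If a majority of rows lack the motif the alignment is
    returned with only trailing all-gap columns removed, and a notice is
    logged.  Trailing all-gap columns are always removed.
    """
    motif = start_motif.upper()
    if not motif:
        raise ValueError("start_motif must be non-empty")
    if GAP in motif:
        raise ValueError("start_motif must be gap-free")

    starts: list[int] = []
    for row in aln.rows:
        col = _motif_start_column(row, motif)
        if col is not None:
            starts.append(col)

    if len(starts) * 2 > aln.n_taxa:
        modal = Counter(starts).most_common()
        # ties broken towards the smaller column (trim less)
        best = min(c for c, k in modal if k == modal[0][1])
        start = best
    else:
        if starts:
            logger.info(
                "start motif %r found in only %d/%d rows; leading columns kept",
                motif, len(starts), aln.n_taxa,
            )
        else:
            logger.info("start motif %r absent; alignment returned unchanged", motif)
        start = 0

    end = aln.length
    while end > start and all(r[end - 1] == GAP for r in aln.rows):
        end -= 1
    if start == 0 and end == aln.length:
        return aln
    return _unchecked_alignment(
        aln.taxa, tuple(r[start:end] for r in aln.rows)
    )


def _motif_start_column(row: str, motif: str) -> Optional[int]:
    """Column of the first base of the motif's first occurrence in the
    ungapped row, or None."""
    residue_cols = [j for j, ch in enumerate(row) if ch != GAP]
    seq = "".join(row[j] for j in residue_cols)
    pos = seq.find(motif)
    if pos < 0:
        return None
    return residue_cols[pos]


# ---------------------------------------------------------------------------
# SupportTree
# ---------------------------------------------------------------------------

class SupportTree:
    """A rooted tree with per-clade support values in ``[0, 1]``.

    Wraps a :class:`dendropy.Tree`.  Support is attached to the child node of
    each internal edge; the root carries none.  ``m`` counts internal nodes
    excluding the root — the resolved nontrivial clades of the consensus.
    """

    def __init__(self, tree: dendropy.Tree):
        tree = tree.clone(depth=1)
        tree.is_rooted = True
        tree.suppress_unifurcations()
        self._tree = tree
        tips = self.tip_labels()
        if len(tips) != len(set(tips)):
            raise TreeFormatError("duplicate tip labels")
        if any(lbl is None or lbl == "" for lbl in tips):
            raise TreeFormatError("unlabelled tips")
        for node in self.internal_nodes():
            s = getattr(node, "support", None)
            if s is not None and not (0.0 <= s <= 1.0):
                raise TreeFormatError(f"support {s} outside [0, 1]")

    # -- structure ---------------------------------------------------------
    @property
    def tree(self) -> dendropy.Tree:
        return self._tree

    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label if leaf.taxon else leaf.label
                for leaf in self._tree.leaf_node_iter()]

    def internal_nodes(self) -> list[dendropy.Node]:
        """Internal nodes excluding the root."""
        root = self._tree.seed_node
        return [nd for nd in self._tree.preorder_node_iter()
                if nd is not root and not nd.is_leaf()]

    @property
    def n(self) -> int:
        return len(self.tip_labels())

    @property
    def m(self) -> int:
        return len(self.internal_nodes())

    def clade_leafsets(self) -> dict[frozenset[str], dendropy.Node]:
        """Map descendant-leaf-label set -> internal node (root excluded)."""
        out: dict[frozenset[str], dendropy.Node] = {}
        for node in self.internal_nodes():
            leafset = frozenset(
                lf.taxon.label if lf.taxon else lf.label
                for lf in node.leaf_iter()
            )
            out[leafset] = node
        return out

    def clade_supports(self) -> dict[frozenset[str], Optional[float]]:
        return {
            clade: getattr(node, "support", None)
            for clade, node in self.clade_leafsets().items()
        }

    # -- serialisation -----------------------------------------------------
    def as_newick(self, support_decimals: int = 4) -> str:
        tree = self._tree.clone(depth=1)
        root = tree.seed_node
        for node in tree.preorder_node_iter():
            if node.is_leaf() or node is root:
                continue
            s = getattr(node, "support", None)
            node.label = (
                None if s is None else f"{round(s, support_decimals):g}"
            )
        return tree.as_string(
            schema="newick", suppress_rooting=True
        ).strip() + "\n"

    def write_newick(self, path: str | Path) -> None:
        Path(path).write_text(self.as_newick())


def _normalise_support(value: float) -> float:
    if not (0.0 <= value <= 100.0):
        raise TreeFormatError(f"support value {value} outside [0, 100]")
    if value > 1.0:
        logger.info("support %s interpreted as a percentage", value)
        return value / 100.0
    return value


_PROB_KEYS = ("prob", "posterior", "pp", "support", "label")
_NUM_RE = re.compile(r"[-+]?\d*\.?\d+(?:[eE][-+]?\d+)?")


def read_support_tree(
    path: str | Path, dialect: str = "newick_labels"
) -> SupportTree:
    """Read a support-annotated consensus tree.

    ``newick_labels``
        Newick whose internal-node labels are numeric supports (posterior
        probabilities or percentages; values in ``(1, 100]`` are rescaled to
        ``[0, 1]`` with a logged notice).
    ``nexus_prob_comments``
        NEXUS trees with bracketed probability comments on nodes, the dialect
        emitted by Bayesian consensus software (``[&prob=0.97]`` and kin).
    """
    if dialect == "newick_labels":
        tree = dendropy.Tree.get(
            path=str(path), schema="newick",
            suppress_internal_node_taxa=True, rooting="force-rooted",
        )
        for node in tree.preorder_node_iter():
            if node.is_leaf():
                continue
            if node.label not in (None, ""):
                node.support = _normalise_support(float(node.label))
                node.label = None
    elif dialect == "nexus_prob_comments":
        tree = dendropy.Tree.get(
            path=str(path), schema="nexus",
            suppress_internal_node_taxa=True, rooting="force-rooted",
            extract_comment_metadata=True,
        )
        for node in tree.preorder_node_iter():
            if node.is_leaf():
                continue
            val = _extract_prob(node)
            if val is not None:
                node.support = _normalise_support(val)
    else:
        raise ValueError(f"unknown tree dialect {dialect!r}")
    return SupportTree(tree)


def _extract_prob(node: dendropy.Node) -> Optional[float]:
    for key in _PROB_KEYS:
        ann = node.annotations.get_value(key, None)
        if ann is not None:
            try:
                return float(ann)
            except (TypeError, ValueError):
                continue
    for comment in node.comments:
        m = _NUM_RE.search(comment)
        if m:
            return float(m.group())
    return None


# ---------------------------------------------------------------------------
# Combined (mixed-datatype) NEXUS
# ---------------------------------------------------------------------------

def write_combined_nexus(aln, indels, path: str | Path) -> None:
    """Write a two-partition NEXUS: nucleotide columns then binary indel
    characters (symbols ``0 1``, ``?`` for missing).

    The file carries a ``datatype=mixed`` declaration in a comment plus an
    executable MrBayes block defining the charsets, the partition, and the
    ascertainment-bias correction for the binary partition (the indel matrix
    contains no constant characters by construction).
    """
    taxa_a, taxa_b = set(aln.taxa), set(indels.taxa)
    if taxa_a != taxa_b:
        diff = sorted(taxa_a.symmetric_difference(taxa_b))
        raise ValueError(f"taxon sets differ between matrices: {diff}")

    n_nt, n_ind = aln.length, len(indels.characters)
    if n_ind == 0:
        logger.info("empty indel matrix: writing nucleotide partition only")
    nchar = n_nt + n_ind
    pad = max(len(sanitize_label(t)) for t in aln.taxa) + 2
    with open(path, "w") as fh:
        fh.write("#NEXUS\n")
        fh.write(f"[ datatype=mixed(DNA:1-{n_nt}"
                 + (f",Standard:{n_nt + 1}-{nchar}" if n_ind else "")
                 + " ]\n\n")
        fh.write("BEGIN DATA;\n")
        fh.write(f"    DIMENSIONS NTAX={aln.n_taxa} NCHAR={nchar};\n")
        fh.write('    FORMAT DATATYPE=STANDARD SYMBOLS="ACGT01" MISSING=? GAP=-;\n')
        fh.write("    MATRIX\n")
        for taxon, row in aln.iter_pairs():
            binary = "".join(str(indels.state(taxon, k)) for k in range(n_ind))
            fh.write(f"    {sanitize_label(taxon):<{pad}}{row}{binary}\n")
        fh.write("    ;\nEND;\n\nBEGIN MRBAYES;\n")
        fh.write(f"    charset nucleotides = 1-{n_nt};\n")
        if n_ind:
            fh.write(f"    charset indels = {n_nt + 1}-{nchar};\n")
            fh.write("    partition bypart = 2:nucleotides,indels;\n")
            fh.write("    set partition=bypart;\n")
            fh.write("    lset applyto=(2) coding=variable;\n")
        else:
            fh.write("    partition bypart = 1:nucleotides;\n")
            fh.write("    set partition=bypart;\n")
        fh.write("END;\n")


def read_combined_nexus(path: str | Path):
    """Read back a combined NEXUS written by :func:`write_combined_nexus`.

    Returns ``(alignment, binary_rows, charsets)`` where ``binary_rows`` maps
    taxon -> 0/1/? string and ``charsets`` maps name -> (start, end) in
    0-based half-open coordinates.
    """
    text = Path(path).read_text()
    charsets: dict[str, tuple[int, int]] = {}
    for m in re.finditer(r"charset\s+(\w+)\s*=\s*(\d+)-(\d+);", text, re.I):
        charsets[m.group(1)] = (int(m.group(2)) - 1, int(m.group(3)))
    matrix = re.search(r"MATRIX\n(.*?)\n\s*;", text, re.S)
    if not matrix:
        raise AlignmentFormatError(f"no MATRIX block in {path}")
    pairs: list[tuple[str, str]] = []
    for line in matrix.group(1).splitlines():
        line = line.strip()
        if line:
            name, row = line.split(None, 1)
            pairs.append((name, row.strip()))
    s, e = charsets["nucleotides"]
    aln = MultipleAlignment.from_pairs((t, r[s:e]) for t, r in pairs)
    binary = {}
    if "indels" in charsets:
        bs, be = charsets["indels"]
        binary = {t: r[bs:be] for t, r in pairs}
    return aln, binary, charsets
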