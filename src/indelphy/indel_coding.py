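"""Simple indel coding and alignment/indel summary statistics.

Simple indel coding turns every distinct internal gap run — identified by its
``(start, end)`` alignment coordinates — into one binary presence/absence
character.  For a character ``c = (s, e)`` and taxon ``t``:

* state ``1`` if ``t`` has a maximal gap run with exactly those coordinates;
* state ``?`` if ``t``'s gap at that place is part of a strictly longer run
  (the indel falls within the range of a longer indel), or if the region
  overlaps a leading/trailing (terminal) gap of ``t`` — terminal gaps are
  missing data, and they never define characters;
* state ``0`` otherwise, including partial, non-containing overlap (the
  classical simple-indel-coding rule).
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Optional

from .io_formats import GAP, MISSING, RESIDUES, MultipleAlignment, sanitize_label

logger = logging.getLogger("indelphy")

SiteClass = Literal["invariant", "variable_uninformative", "parsimony_informative"]

#: symbols ignored when classifying nucleotide sites
_SITE_MISSING = frozenset("-?N")


# ---------------------------------------------------------------------------
# Gap runs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GapRun:
    """A maximal run of ``-`` in one row; ``[start, end)`` columns."""

    taxon: str
    start: int
    end: int
    terminal: bool

    @property
    def length(self) -> int:
        return self.end - self.start


def extract_gap_runs(aln: MultipleAlignment) -> list[GapRun]:
    """All maximal gap runs, flagged terminal when they touch either
    alignment end; sorted by (taxon order, start)."""
    runs: list[GapRun] = []
    L = aln.length
    for taxon, row in aln.iter_pairs():
        j = 0
        while j < L:
            if row[j] == GAP:
                start = j
                while j < L and row[j] == GAP:
                    j += 1
                runs.append(GapRun(taxon, start, j, start == 0 or j == L))
            else:
                j += 1
    return runs


# ---------------------------------------------------------------------------
# Characters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IndelCharacter:
    start: int
    end: int
    states: dict[str, object]  # taxon -> 0 | 1 | '?'

    @property
    def length(self) -> int:
        return self.end - self.start

    def __hash__(self):  # states dict is effectively immutable after build
        return hash((self.start, self.end))


@dataclass(frozen=True)
class IndelCharacterMatrix:
    taxa: tuple[str, ...]
    characters: tuple[IndelCharacter, ...]

    def state(self, taxon: str, k: int):
        return self.characters[k].states[taxon]

    def states_row(self, taxon: str) -> str:
        return "".join(str(c.states[taxon]) for c in self.characters)

    @property
    def n_characters(self) -> int:
        return len(self.characters)

    def coordinates(self) -> list[tuple[int, int]]:
        return [(c.start, c.end) for c in self.characters]


def simple_indel_coding(aln: MultipleAlignment) -> IndelCharacterMatrix:
    """Code all indels with distinct start and/or end positions as binary
    presence/absence characters (see module docstring for the state rules)."""
    runs = extract_gap_runs(aln)
    by_taxon: dict[str, list[GapRun]] = {t: [] for t in aln.taxa}
    for r in runs:
        by_taxon[r.taxon].append(r)

    coords = sorted({(r.start, r.end) for r in runs if not r.terminal})
    characters = []
    for (s, e) in coords:
        states: dict[str, object] = {}
        for taxon in aln.taxa:
            states[taxon] = _score(s, e, by_taxon[taxon])
        characters.append(IndelCharacter(s, e, states))
    return IndelCharacterMatrix(aln.taxa, tuple(characters))


def _score(s: int, e: int, runs: list[GapRun]):
    for r in runs:
        if r.terminal:
            if r.start < e and s < r.end:  # any overlap with a terminal gap
                return MISSING
        else:
            if r.start == s and r.end == e:
                return 1
            if r.start <= s and e <= r.end:  # strictly longer covering run
                return MISSING
    return 0


# ---------------------------------------------------------------------------
# Site and character classification
# ---------------------------------------------------------------------------

def classify_sites(aln: MultipleAlignment) -> list[SiteClass]:
    """Per-column class; ``-``, ``?`` and ``N`` are ignored as missing."""
    out: list[SiteClass] = []
    for j in range(aln.length):
        col = [ch for ch in aln.column(j) if ch not in _SITE_MISSING]
        if len(col) < 2:
            logger.debug("column %d has <2 scored symbols; classed invariant", j)
            out.append("invariant")
            continue
        counts = Counter(col)
        if len(counts) < 2:
            out.append("invariant")
        elif sum(1 for c in counts.values() if c >= 2) >= 2:
            out.append("parsimony_informative")
        else:
            out.append("variable_uninformative")
    return out


def classify_indel_characters(m: IndelCharacterMatrix) -> list[SiteClass]:
    """Same two-state definition over {0,1}, '?' ignored."""
    out: list[SiteClass] = []
    for c in m.characters:
        counts = Counter(v for v in c.states.values() if v in (0, 1))
        if len(counts) < 2:
            out.append("invariant")
        elif all(k >= 2 for k in counts.values()):
            out.append("parsimony_informative")
        else:
            out.append("variable_uninformative")
    return out


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SiteSummary:
    """Alignment/indel statistics: counts of variable and parsimony-
    informative nucleotide sites, indel characters by informativeness class,
    and mean indel lengths per class (NaN when a class is empty)."""

    alignment_length: int
    n_variable_sites: int
    n_informative_sites: int
    n_indel_characters: int
    n_variable_indels: int
    n_informative_indels: int
    mean_indel_length: float
    mean_informative_indel_length: float
    mean_uninformative_indel_length: float


def summarize(
    aln: MultipleAlignment, m: IndelCharacterMatrix
) -> tuple[SiteSummary, dict[str, Counter]]:
    """Site/indel summary plus per-class indel-length histograms
    (class -> Counter over integer lengths >= 1)."""
    site_classes = classify_sites(aln)
    char_classes = classify_indel_characters(m)
    lengths = [c.length for c in m.characters]

    hist: dict[str, Counter] = {"all": Counter(), "parsimony_informative": Counter(),
                                "variable_uninformative": Counter(), "invariant": Counter()}
    for length, cls in zip(lengths, char_classes):
        hist["all"][length] += 1
        hist[cls][length] += 1

    def _mean(vals: list[int]) -> float:
        return sum(vals) / len(vals) if vals else math.nan

    pi_len = [l for l, c in zip(lengths, char_classes) if c == "parsimony_informative"]
    un_len = [l for l, c in zip(lengths, char_classes) if c != "parsimony_informative"]

    summary = SiteSummary(
        alignment_length=aln.length,
        n_variable_sites=sum(c != "invariant" for c in site_classes),
        n_informative_sites=sum(c == "parsimony_informative" for c in site_classes),
        n_indel_characters=len(lengths),
        n_variable_indels=sum(c != "invariant" for c in char_classes),
        n_informative_indels=len(pi_len),
        mean_indel_length=_mean(lengths),
        mean_informative_indel_length=_mean(pi_len),
        mean_uninformative_indel_length=_mean(un_len),
    )
    return summary, hist


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------

def write_indel_nexus(m: IndelCharacterMatrix, path: str | Path) -> None:
    """Standalone binary matrix (datatype=standard, symbols \"01\")."""
    pad = max(len(sanitize_label(t)) for t in m.taxa) + 2
    with open(path, "w") as fh:
        fh.write("#NEXUS\n\nBEGIN DATA;\n")
        fh.write(f"    DIMENSIONS NTAX={len(m.taxa)} NCHAR={m.n_characters};\n")
        fh.write('    FORMAT DATATYPE=STANDARD SYMBOLS="01" MISSING=?;\n    MATRIX\n')
        for t in m.taxa:
            fh.write(f"    {sanitize_label(t):<{pad}}{m.states_row(t)}\n")
        fh.write("    ;\nEND;\n")


def write_indel_tsv(m: IndelCharacterMatrix, path: str | Path) -> None:
    """Taxa x characters TSV with [start,end) coordinates in the header."""
    with open(path, "w") as fh:
        header = "\t".join(f"{c.start}:{c.end}" for c in m.characters)
        fh.write("taxon\t" + header + "\n")
        for t in m.taxa:
            fh.write(t + "\t" + "\t".join(str(c.states[t]) for c in m.characters) + "\n")
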