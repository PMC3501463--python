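# Methods

This note documents the models and procedures `indelphy` implements, the
parameters that matter, and the choices made where the design was genuinely
open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Coordinates and containers

Alignment columns are 0-based, half-open `[start, end)` everywhere.
Alignments are taxa-by-columns matrices over `{A,C,G,T,N,?,-}`; IUPAC
ambiguity codes collapse to `N` on read (with a logged warning), `U` maps
to `T`. Trees are rooted throughout; clade support lives on the child node
of each internal edge, the root carries none, and `m` counts internal
non-root nodes (so a fully resolved rooted tree has `m = n − 2` and
resolution `m/(n−2) = 1`). A root with a single child is collapsed on
read; a two-child root is a legitimate rooted-binary root and is kept.

## Terminal trimming

ITS matrices are conventionally trimmed to start at the conserved `CATTA`
motif at the 3' end of 18S. The motif is located on each row's ungapped
sequence and mapped back to the alignment column of its first base;
columns before the *modal* first-match column are removed. When the motif
is found in half the rows or fewer, nothing is trimmed (logged). Behaviour
when only some rows contain the motif is a convention of this package, not
a property of the data: the modal rule trims by the majority's coordinate
and leaves ragged minorities intact. Trailing all-gap columns are always
removed.

## Simple indel coding

Every maximal run of `-` in a row is a gap run; runs touching the first or
last column are *terminal*. Each distinct internal `(start, end)` pair
defines one binary character, ordered lexicographically. For character
`(s, e)` and taxon `t`:

1. `1` if `t` has a maximal internal run with exactly those coordinates;
2. `?` if `t`'s gap there is part of a strictly longer run (an indel
   falling within the range of a longer indel is unknowable), or if
   `[s, e)` overlaps a terminal run of `t` (leading/trailing gaps are
   missing data, usually sequencing artefacts rather than evolution);
3. `0` otherwise — including partial, non-containing overlap, the
   classical simple-indel-coding convention.

Terminal runs never *define* characters; a taxon whose run matches a
character's coordinates but touches the alignment edge scores `?` while
internal carriers score `1`. How the original coding tools treat a region
*partially* overlapping a terminal gap is not documented anywhere we could
verify; this package scores `?` on any overlap, which is the conservative
choice (it discards rather than invents information) and is flagged for
sensitivity analysis rather than asserted as canonical.

Site classification ignores `-`, `?` and `N`: a column is variable with
≥2 residue states among scored symbols and parsimony-informative when ≥2
states each occur in ≥2 taxa; the same two-state definition applies to the
binary characters with `?` ignored.

## Block filtering

Columns are classed by gap fraction and conservation: a column with gap
fraction above `max_gap_fraction` (default 0.5; ties retained) is
gap-excluded, otherwise the frequency `f` of its most common residue
(denominator includes gapped rows — a gap is not a residue but counts in
the total, the stricter reading) makes it non-conserved
(`f < min_conserved_fraction`), conserved, or highly conserved
(`f ≥ 0.85`). `min_conserved_fraction` defaults to "strictly more than
half the sequences" (`⌊n/2⌋+1` of `n`). Blocks are then selected in four
ordered steps: (1) reject stretches of more than
`max_contiguous_nonconserved` (default 15) contiguous
non-conserved-or-gap-excluded columns; (2) trim each surviving segment
inward to the nearest highly conserved column; (3) reject every
gap-excluded column and any non-conserved column contiguous with one;
(4) drop blocks shorter than `min_block_length` (default 5).

Byte-compatibility with any particular filtering program is not a goal;
the four steps above are this package's normative definition, with
defaults matching the documented defaults of the classic tool's "less
stringent" usage. Because step 3 runs after the end-trimming of step 2, a
block can end on a merely-conserved column; re-filtering a block is
therefore idempotent on its highly-conserved core, not byte-for-byte —
the tests assert exactly that. The conserved/flank thresholds are
configurable because the "less stringent" convention fixes only the three
values above.

## Support surrogate

Bayesian tree estimation is deliberately out of scope. Supports come from
a desk-scale surrogate: pairwise p-distances (mismatch proportion over
pairwise-comparable positions; with an indel partition, nucleotide columns
and binary characters pool with weights proportional to the number of
compared positions per pair), neighbor joining with a deterministic
lexicographic tie-break and negative branch lengths clamped to zero, and a
nonparametric bootstrap whose resampling is stratified by partition so
each replicate preserves the nucleotide/indel evidence proportions.
Replicate trees are rooted on the pendant edge of the lexicographically
smallest taxon (edge split in half) so clades are comparable across
replicates; the majority-rule consensus (frequency strictly > 0.5) carries
clade frequencies as supports and mean edge lengths over the trees
containing each clade.

Everything these trees carry is a **bootstrap proportion**; the package
never labels them posterior probabilities. Externally computed Bayesian
consensus trees (Newick with support labels, or NEXUS with bracketed
probability comments) can be injected per treatment instead.

One numerical choice deserves emphasis: within bootstrap replicates,
internal NJ edges of (clamped) zero length are collapsed before clades are
counted. NJ always returns a fully resolved topology, so resolution backed
by no character at all appears as zero-length edges; with a deterministic
tie-break those arbitrary resolutions repeat identically in every
replicate and would otherwise masquerade as 100% support. Collapsing them
makes a signal-free alignment yield an unresolved consensus, which is the
honest answer. The public `neighbor_joining` function keeps full
resolution (its contract is the classical algorithm).

The rooting convention means the clade "everything except the root taxon"
appears in every replicate and so always carries support 1.0 — a known,
treatment-symmetric artefact analogous to an always-recovered outgroup
split.

## Tree statistics

Tree support is `resolution × mean support`; a completely unresolved tree
scores 0 (a polytomy contributes nothing). Node depth is the mean
branch-length path from a node to its descendant leaves (tips have depth
0). Depth-support profiles bin the pooled points into `K` equal-width
bins over the observed depth range (default `K = 800`; the right edge is
inclusive in the last bin), and the count-weighted mean of bin means
equals the global mean by construction. Congruence between two consensus
trees compares clades — descendant sets, not unrooted bipartitions — and
support ratios are reported as combined/nucleotide-only, so values above 1
favour the indel-including analysis. Signal decay is an ordinary least
squares fit of support on depth (slope, intercept, standard errors, R²).

## Synthetic data

The generator emulates an ITS-like locus: three contiguous regions —
flank1 / core / flank2, default root lengths 80 / 100 / 80 nt (a
desk-scale ITS1 / 5.8S / ITS2) — with per-region rate multipliers for
substitutions and indels. Trees are Yule: while `k` lineages exist the
next speciation is Exponential(`k·λ`) and splits a uniform lineage; after
the `n`-th lineage one further interval runs to the present, so pendant
branches are never zero. Substitutions follow a single-parameter symmetric
(Jukes–Cantor-type) model applied per branch with change probability
`¾(1 − e^(−4/3·μt))`. Indel events arrive as a Poisson process with mean
`indel_rate × multiplier × region length × branch length`; lengths follow
geometric(0.5) by default (mode 1, heavy right tail — the shape of
empirical indel-length spectra) with a zeta option; insertion vs deletion
is Bernoulli(`insertion_fraction`). Deletions truncate at region
boundaries so region identity is stable across the tree; a region driven
to zero residues raises an error advising a lower rate.

Positional homology in the emitted alignment is exact by construction:
every insertion opens fresh columns in a global column register, so two
residues share a column only if they descend from the same root or
inserted residue, and no re-alignment step ever runs. Every indel event is
logged with its branch, type, final-alignment coordinates and length.
This is what makes coding-recovery tests exact: in deletion-only runs
whose events neither touch the alignment ends nor share/nest boundaries,
coded characters correspond one-to-one to logged events.

What the generator does **not** emulate: alignment error (the true
alignment is handed to the pipeline directly, so effects attributable to
aligner behaviour are invisible here), rate heterogeneity within regions,
secondary-structure constraints, base-composition bias, and sequencing
artefacts. Passing directional tests on these data therefore shows that
the pipeline orders treatments correctly when indels carry genuine
homologous signal; it does not show how large the effects are on real
alignments.

### Study conditions

`saturated_flank_params()` fixes the regime used by the directional
checks: 12 tips, unit birth rate, flank substitution multiplier 2.0
(≈3–4 expected substitutions per site root-to-tip, so flank distances
saturate at deep divergences while recent splits stay informative), core
multiplier 0.01 (near-invariant, like 5.8S), indel rate 0.08 per site per
unit time confined to the flanks. This yields on the order of 50 indel
events and ~100–150 binary characters against ~200 variable nucleotide
sites — indel mutation events are roughly 40× rarer than substitutions,
and the character-to-variable-site ratio matches what indel-coded spacer
alignments typically show. Each indel character is (near-)homoplasy-free,
which is precisely the "length mutations are more conserved than
nucleotide changes" premise under test.

The directional analyses use 50 replicates (plus 100 more for decay
batches of 3 pooled datasets each) at bootstrap `B = 100` — sizes chosen
so the whole comparison runs in tens of seconds on one CPU while leaving
the directional contrasts far from their decision thresholds.

The decay comparison is computed on congruent nodes. On the full
resolved-node collections a survivorship artefact dominates at this scale:
the nucleotide-only consensus collapses its weakest deep nodes, deleting
exactly the low-support deep points and biasing its apparent slope
shallow. Congruent nodes compare like with like; the profile machinery
reports both collections.

The comparison report pools depth-support points per treatment both by
node and with datasets weighted equally (weight `1/n_nodes` within each
dataset), since pooling many datasets onto one depth axis otherwise lets
node-rich datasets dominate.

## Known limitations

- p-distance + NJ is a crude estimator; it underestimates deep divergence
  and the surrogate supports are not interchangeable with posterior
  probabilities. The package's claims are directional comparisons between
  treatments run under identical machinery.
- The combined distance weights indel characters by count, so a small
  character set moves combined distances only slightly; treatments are
  compared at matched `B` and seed to keep this fair.
- The indels-only treatment can fail for taxon pairs with no mutually
  scored characters; it is skipped (and logged) rather than imputed.
- `m/(n−2)` treats the root as unresolvable structure; trees rooted on a
  tip edge by the surrogate include the "all but root taxon" clade in `m`,
  which is consistent across treatments but inflates absolute resolution
  by up to `1/(n−2)` relative to conventions that drop that clade.
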