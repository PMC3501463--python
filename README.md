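# indelphy

Tools for asking a practical question in molecular phylogenetics: **do
alignment gaps help or hurt?** Fast nuclear markers such as the ribosomal
internal transcribed spacers (ITS1/ITS2, flanking the conserved 5.8S gene)
are rich in insertions and deletions. Common practice either throws the
gapped regions away (block filtering à la Gblocks), treats gaps as missing
data, or recodes indels as extra binary characters (simple indel coding) and
analyses them alongside the nucleotides. `indelphy` implements all three
treatments and the statistics needed to compare them, plus a sequence
simulator with exact indel ground truth, so the whole comparison runs
end-to-end on synthetic data with no external programs.

It is aimed at systematists and methods developers who want a tested,
scriptable implementation of:

- **simple indel coding** — every internal maximal gap run with distinct
  `(start, end)` coordinates becomes one presence/absence character; a gap
  nested inside a longer gap scores `?` (unknown), and leading/trailing gaps
  are missing data;
- **block filtering** — a Gblocks-style four-step exclusion of gap-rich and
  non-conserved regions (defaults: ≤15 contiguous non-conserved positions,
  minimum block length 5, at most half the sequences gapped per site);
- **tree-level signal statistics** — resolution `m/(n−2)` (resolved
  non-trivial clades over the maximum for `n` tips), mean clade support, and
  their product ("tree support", 1.0 exactly for a fully resolved,
  unanimously supported consensus); node depth (mean branch-length path from
  a node to its descendant leaves); depth-binned support profiles (default
  800 categories); congruent-clade support ratios between two consensus
  trees; and an OLS fit of support against depth (signal decay);
- **a support surrogate** — p-distances, neighbor joining, and a
  partition-stratified nonparametric bootstrap (nucleotide columns and indel
  characters resampled independently). The supports it reports are bootstrap
  proportions, not posterior probabilities; externally computed Bayesian
  consensus trees can be injected instead;
- **a synthetic-data generator** — Yule trees and sequence evolution with a
  conserved core and indel-rich flanks, with the true alignment and every
  indel event logged exactly.

## Worked example

```python
from indelphy import (
    saturated_flank_params, simulate_dataset, simple_indel_coding,
    summarize, PipelineConfig, run_dataset,
)

truth = simulate_dataset(saturated_flank_params(seed=11))
indels = simple_indel_coding(truth.alignment)
stats, _ = summarize(truth.alignment, indels)
print(f"alignment: {truth.alignment.n_taxa} taxa x {stats.alignment_length} columns")
print(f"variable sites: {stats.n_variable_sites}  "
      f"parsimony-informative: {stats.n_informative_sites}")
print(f"indel characters: {stats.n_indel_characters}  "
      f"informative: {stats.n_informative_indels}  "
      f"mean length: {stats.mean_indel_length:.2f}")

config = PipelineConfig(B=100, seed=1)
for r in run_dataset(truth.alignment, config, "demo"):
    s = r.summary
    print(f"{r.treatment:>15}: resolution={s.resolution:.2f} "
          f"mean_support={s.mean_support:.2f} tree_support={s.tree_support:.2f}")
```

prints

```
alignment: 12 taxa x 397 columns
variable sites: 227  parsimony-informative: 169
indel characters: 148  informative: 60  mean length: 3.40
        nt_only: resolution=0.40 mean_support=0.89 tree_support=0.36
 nt_plus_indels: resolution=0.90 mean_support=0.89 tree_support=0.80
         masked: resolution=0.30 mean_support=0.75 tree_support=0.22
    indels_only: resolution=0.80 mean_support=0.94 tree_support=0.76
```

The simulated alignment has substitution-saturated flanks, a near-invariant
core and 148 binary indel characters. Nucleotide-only analysis resolves 40%
of clades; adding the indel partition lifts resolution to 90% at unchanged
mean support, so tree support rises from 0.36 to 0.80. Masking the
ambiguous (flank) regions leaves mostly the conserved core and support
drops — the two directional effects the package is built to measure.

A `indelphy` console command exposes the same stages (`simulate`, `trim`,
`code-indels`, `mask`, `support`, `treestats`, `run-all`); see
`indelphy --help`.

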