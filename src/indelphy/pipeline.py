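"""Orchestration of the four-treatment comparison.

For each dataset the pipeline builds consensus trees with supports under
four treatments of gapped sites:

* ``nt_only`` — nucleotide columns, gaps treated as missing;
* ``nt_plus_indels`` — nucleotides plus the binary simple-indel-coding
  matrix, as two partitions;
* ``masked`` — nucleotides after block filtering of ambiguously aligned
  regions;
* ``indels_only`` — the binary indel matrix alone.

Supports come from the partitioned bootstrap surrogate (or from an injected
externally computed consensus tree).  The comparison report aggregates
tree-support summaries, pooled depth-support profiles, congruent-node
support ratios and decay regressions across datasets.
"""

from __future__ import annotations

import json
import logging
import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import block_filter, indel_coding, io_formats, support_estimation, tree_metrics
from .block_filter import BlockParams
from .indel_coding import IndelCharacterMatrix
from .io_formats import MultipleAlignment, SupportTree

logger = logging.getLogger("indelphy")

TREATMENTS = ("nt_only", "nt_plus_indels", "masked", "indels_only")


@dataclass(frozen=True)
class PipelineConfig:
    """Batch settings; every run is reproducible from ``seed``."""

    B: int = 100                       # bootstrap replicates
    K: int = 800                       # depth categories for profiles
    seed: int = 0
    block_params: BlockParams = field(default_factory=BlockParams)
    trim_motif: Optional[str] = None   # e.g. "CATTA"; None skips trimming
    treatments: tuple[str, ...] = TREATMENTS
    external_trees: dict = field(default_factory=dict)  # treatment -> tree path

    def to_json(self) -> str:
        d = {
            "B": self.B, "K": self.K, "seed": self.seed,
            "block_params": vars(self.block_params).copy(),
            "trim_motif": self.trim_motif,
            "treatments": list(self.treatments),
            "external_trees": dict(self.external_trees),
        }
        return json.dumps(d, indent=2, sort_keys=True)


@dataclass
class TreatmentResult:
    dataset_id: str
    treatment: str
    tree: SupportTree
    summary: tree_metrics.TreeSupportSummary
    nodes: list[tuple[float, float]]   # (depth, support) per resolved clade


def _treatment_seed(seed: int, dataset_id: str, treatment: str) -> int:
    # stable sub-seed per dataset x treatment, kept below 2**31
    h = zlib.crc32(f"{dataset_id}/{treatment}".encode())
    return (seed * 1_000_003 + h) % (2**31 - 1)


def run_dataset(
    aln: MultipleAlignment | str | Path,
    config: PipelineConfig,
    dataset_id: str = "dataset",
    outdir: Optional[str | Path] = None,
) -> list[TreatmentResult]:
    """Run all configured treatments on one alignment.

    Accepts an alignment object or a FASTA/NEXUS path.  A gap-free
    alignment degrades ``nt_plus_indels`` to ``nt_only`` with a logged
    notice and skips ``indels_only``.
    """
    if not isinstance(aln, MultipleAlignment):
        path = Path(aln)
        fmt = "nexus" if path.suffix.lower() in (".nex", ".nexus") else "fasta"
        aln = io_formats.read_alignment(path, fmt)
    if config.trim_motif:
        aln = io_formats.trim_terminal_overhangs(aln, config.trim_motif)

    indels = indel_coding.simple_indel_coding(aln)
    mask = block_filter.select_blocks(aln, config.block_params)
    masked_aln = block_filter.apply_mask(aln, mask)

    results: list[TreatmentResult] = []
    for treatment in config.treatments:
        try:
            tree = _treatment_tree(
                aln, indels, masked_aln, treatment, config, dataset_id
            )
        except _SkipTreatment as exc:
            logger.info("%s/%s skipped: %s", dataset_id, treatment, exc)
            continue
        summary = tree_metrics.tree_support(tree)
        nodes = tree_metrics.depth_support_points(tree)
        results.append(TreatmentResult(dataset_id, treatment, tree, summary, nodes))

    if outdir is not None:
        _write_results(results, aln, indels, mask, config, Path(outdir))
    return results


class _SkipTreatment(Exception):
    pass


def _treatment_tree(
    aln: MultipleAlignment,
    indels: IndelCharacterMatrix,
    masked_aln: MultipleAlignment,
    treatment: str,
    config: PipelineConfig,
    dataset_id: str,
) -> SupportTree:
    if treatment in config.external_trees:
        return io_formats.read_support_tree(config.external_trees[treatment])
    seed = _treatment_seed(config.seed, dataset_id, treatment)
    if treatment == "nt_only":
        return support_estimation.bootstrap_support(aln, None, config.B, seed)
    if treatment == "nt_plus_indels":
        if indels.n_characters == 0:
            logger.info(
                "%s: no indel characters; nt_plus_indels degrades to nt_only",
                dataset_id,
            )
            seed = _treatment_seed(config.seed, dataset_id, "nt_only")
            return support_estimation.bootstrap_support(aln, None, config.B, seed)
        return support_estimation.bootstrap_support(aln, indels, config.B, seed)
    if treatment == "masked":
        if masked_aln.length == 0:
            raise _SkipTreatment("block filter retained no columns")
        return support_estimation.bootstrap_support(masked_aln, None, config.B, seed)
    if treatment == "indels_only":
        if indels.n_characters == 0:
            raise _SkipTreatment("no indel characters")
        try:
            return support_estimation.bootstrap_support_indels_only(
                indels, config.B, seed
            )
        except ValueError as exc:
            raise _SkipTreatment(str(exc))
    raise ValueError(f"unknown treatment {treatment!r}")


def run_batch(
    datasets: Sequence[tuple[str, MultipleAlignment | str | Path]],
    config: PipelineConfig,
    outdir: Optional[str | Path] = None,
) -> tuple[list[TreatmentResult], list[dict]]:
    """Run many datasets; one dataset's failure never aborts the batch.

    Returns (results, failures); each failure is a structured record with
    the dataset id and the error message.
    """
    results: list[TreatmentResult] = []
    failures: list[dict] = []
    for dataset_id, aln in datasets:
        sub = Path(outdir) / dataset_id if outdir is not None else None
        try:
            results.extend(run_dataset(aln, config, dataset_id, sub))
        except Exception as exc:  # noqa: BLE001 - error isolation contract
            logger.error("dataset %s failed: %s", dataset_id, exc)
            failures.append({"dataset": dataset_id, "error": str(exc)})
    return results, failures


# ---------------------------------------------------------------------------
# Comparison report
# ---------------------------------------------------------------------------

def compare_treatments(
    results: Sequence[TreatmentResult], K: int = 800
) -> dict:
    """Aggregate treatment results into a comparison report.

    The report holds: a per-dataset/treatment summary table; per-treatment
    pooled (depth, support) profiles and decay regressions — pooled both by
    node and with datasets weighted equally; congruent-node support ratios
    between ``nt_only`` and ``nt_plus_indels`` (ratio = combined / nt-only,
    so values > 1 favour the indel-including analysis).
    """
    if not results:
        raise ValueError("no treatment results")
    rows = []
    for r in results:
        s = r.summary
        rows.append({
            "dataset": r.dataset_id, "treatment": r.treatment,
            "n": s.n, "m": s.m, "resolution": s.resolution,
            "mean_support": s.mean_support, "tree_support": s.tree_support,
        })
    summary_df = pd.DataFrame(rows)

    by_treatment: dict[str, list[TreatmentResult]] = {}
    for r in results:
        by_treatment.setdefault(r.treatment, []).append(r)

    profiles, decay, decay_weighted = {}, {}, {}
    for treatment, rs in by_treatment.items():
        points = [pt for r in rs for pt in r.nodes]
        if points:
            profiles[treatment] = tree_metrics.bin_depth_support(points, K)
        # node-pooled OLS
        try:
            decay[treatment] = tree_metrics.decay_regression(points)
        except ValueError:
            decay[treatment] = None
        # equal dataset weights: every dataset contributes its node-mean
        # structure via per-dataset replication weights
        wpoints = []
        for r in rs:
            if r.nodes:
                w = 1.0 / len(r.nodes)
                wpoints.append((r, w))
        decay_weighted[treatment] = _weighted_decay(wpoints)

    ratios = []
    paired = {}
    for r in results:
        paired.setdefault(r.dataset_id, {})[r.treatment] = r
    for dataset_id, trees in sorted(paired.items()):
        if "nt_only" in trees and "nt_plus_indels" in trees:
            pairs = tree_metrics.congruent_clades(
                trees["nt_only"].tree, trees["nt_plus_indels"].tree
            )
            for p in pairs:
                ratios.append({
                    "dataset": dataset_id,
                    "clade_size": len(p.clade),
                    "support_nt": p.support_a,
                    "support_combined": p.support_b,
                    "ratio": p.ratio,
                })
    ratio_df = pd.DataFrame(ratios)

    mean_support = (
        summary_df.groupby("treatment")["tree_support"].mean().to_dict()
    )
    return {
        "summary": summary_df,
        "mean_tree_support": mean_support,
        "profiles": profiles,
        "decay": decay,
        "decay_weighted": decay_weighted,
        "congruent_ratios": ratio_df,
    }


def _weighted_decay(weighted: list) -> Optional[tree_metrics.DecayFit]:
    """WLS decay fit with datasets weighted equally (weight 1/n_nodes per
    node), via the closed-form weighted normal equations."""
    xs, ys, ws = [], [], []
    for r, w in weighted:
        for (d, s) in r.nodes:
            xs.append(d)
            ys.append(s)
            ws.append(w)
    if len(xs) < 3 or len(set(xs)) < 2:
        return None
    import numpy as np

    x, y, w = map(np.asarray, (xs, ys, ws))
    W = w.sum()
    xbar, ybar = (w * x).sum() / W, (w * y).sum() / W
    sxx = (w * (x - xbar) ** 2).sum()
    sxy = (w * (x - xbar) * (y - ybar)).sum()
    if sxx == 0:
        return None
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    resid = y - intercept - slope * x
    dof = max(len(xs) - 2, 1)
    s2 = (w * resid**2).sum() / dof
    syy = (w * (y - ybar) ** 2).sum()
    r2 = 0.0 if syy == 0 else 1.0 - (w * resid**2).sum() / syy
    return tree_metrics.DecayFit(
        slope=float(slope), intercept=float(intercept),
        slope_se=float(math.sqrt(s2 / sxx)),
        intercept_se=float(math.sqrt(s2 * (1 / W + xbar**2 / sxx))),
        r_squared=float(r2),
    )


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------

def _write_results(results, aln, indels, mask, config, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    io_formats.write_fasta(aln, outdir / "alignment.fasta")
    indel_coding.write_indel_tsv(indels, outdir / "indels.tsv")
    block_filter.write_mask_tsv(mask, outdir / "mask.tsv")
    if indels.n_characters:
        io_formats.write_combined_nexus(aln, indels, outdir / "combined.nex")
    (outdir / "config.json").write_text(config.to_json())
    rows = []
    for r in results:
        r.tree.write_newick(outdir / f"{r.treatment}.nwk")
        s = r.summary
        rows.append(
            f"{r.treatment}\t{s.n}\t{s.m}\t{s.resolution:.6g}"
            f"\t{s.mean_support:.6g}\t{s.tree_support:.6g}"
        )
        with open(outdir / f"{r.treatment}_nodes.tsv", "w") as fh:
            fh.write("depth\tsupport\n")
            for d, sup in r.nodes:
                fh.write(f"{d:.8g}\t{sup:.8g}\n")
    with open(outdir / "summary.tsv", "w") as fh:
        fh.write("treatment\tn\tm\tresolution\tmean_support\ttree_support\n")
        fh.write("\n".join(rows) + "\n")


def write_report(report: dict, outdir: str | Path) -> None:
    """Write the comparison report as tidy TSV tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report["summary"].to_csv(outdir / "tree_support.tsv", sep="\t", index=False)
    if len(report["congruent_ratios"]):
        report["congruent_ratios"].to_csv(
            outdir / "congruent_ratios.tsv", sep="\t", index=False
        )
    rows = []
    for treatment, fit in report["decay"].items():
        wfit = report["decay_weighted"].get(treatment)
        if fit is None:
            continue
        rows.append({
            "treatment": treatment,
            "slope": fit.slope, "slope_se": fit.slope_se,
            "intercept": fit.intercept, "r_squared": fit.r_squared,
            "slope_dataset_weighted": None if wfit is None else wfit.slope,
        })
    pd.DataFrame(rows).to_csv(outdir / "decay.tsv", sep="\t", index=False)
    for treatment, profile in report["profiles"].items():
        with open(outdir / f"profile_{treatment}.tsv", "w") as fh:
            fh.write("bin_start\tbin_end\tcount\tmean_support\n")
            for k in range(profile.K):
                fh.write(
                    f"{profile.edges[k]:.8g}\t{profile.edges[k + 1]:.8g}"
                    f"\t{profile.counts[k]}\t{profile.means[k]:.8g}\n"
                )
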