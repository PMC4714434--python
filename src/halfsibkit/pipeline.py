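"""Config-driven orchestration of the full synthetic analysis pipeline.

Stages run in dependency order: simulate -> prep -> {kinship, pad, discan}
-> trees; the overlap chi-square and the G-test stages are independent and
run from counts given in the config.  Every output file is recorded in a
JSON manifest with its SHA-256 checksum, so identical config + seed yields
identical manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as hio
from .categorical import ContingencyTable2xK, backward_elimination_g, chi_square_2x2, g_test, overlap_2x2
from .datatypes import MatrixKind
from .discan import permutation_null, scan_size_markers
from .expression import compute_rpkm, filter_low_expression, high_expression_subset
from .kinship import cssc_distance_matrix
from .njtree import neighbor_joining, write_newick
from .pad import median_ratio_adjust, pad_matrix
from .simulate import simulate_counts, simulate_pedigree

__all__ = ["PipelineConfig", "run_pipeline"]

_ALL_STAGES = ("simulate", "prep", "kinship", "pad", "discan", "overlap", "gotest")


@dataclass
class PipelineConfig:
    """All thresholds, seeds and stage selections for one pipeline run."""

    stages: list[str] = field(default_factory=lambda: ["simulate", "prep", "kinship", "pad", "discan"])
    seed: int = 0
    out_dir: str = "halfsibkit_out"
    # simulate
    n_markers: int = 2000
    maf_low: float = 0.1
    maf_high: float = 0.5
    n_planted: int = 5
    missing_rate: float = 0.0
    n_contigs: int = 5000
    frac_season_de: float = 0.1
    frac_size_de: float = 0.05
    log2fc: float = 1.5
    dispersion: float = 0.29**2
    # prep filters
    min_expressing_fish: int = 4
    min_total_cpm: float = 1.0
    min_rpkm: float = 5.0
    min_fish: int = 2
    # DI scan
    di_threshold: float = 0.89
    min_informative: int = 9
    di_criterion: str = "strict"
    n_perm: int = 0
    # PAD
    pad_transform: str = "capped"
    pad_high_expression_only: bool = True
    # category tests
    alpha: float = 0.05
    williams: bool = False
    overlap_counts: list[int] | None = None  # [sept∩small, dec∩small, sept∩large, dec∩large]
    gotest_counts: list[list[int]] | None = None
    gotest_categories: list[str] | None = None
    # external inputs (used when simulate is not selected)
    genotypes_path: str | None = None
    counts_path: str | None = None
    samples_path: str | None = None

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        return cls(**(yaml.safe_load(text) or {}))

    def validate(self) -> None:
        unknown = set(self.stages) - set(_ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if not (0 <= self.di_threshold <= 1):
            raise ValueError("di_threshold must lie in [0, 1]")
        if self.alpha <= 0 or self.alpha >= 1:
            raise ValueError("alpha must lie in (0, 1)")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the selected stages and return the output manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "parameters": dataclasses.asdict(config),
        "stages": list(config.stages),
        "outputs": {},
        "results": {},
    }

    def emit(name: str, path: Path) -> None:
        manifest["outputs"][name] = {"path": str(path), "sha256": _sha256(path)}

    genotypes = counts = samples = None

    if "simulate" in config.stages:
        genotypes_full, samples, truth_g = simulate_pedigree(
            n_markers=config.n_markers,
            maf_low=config.maf_low,
            maf_high=config.maf_high,
            n_planted=config.n_planted,
            missing_rate=config.missing_rate,
            seed=config.seed,
        )
        counts, truth_c = simulate_counts(
            n_contigs=config.n_contigs,
            frac_season_de=config.frac_season_de,
            frac_size_de=config.frac_size_de,
            log2fc=config.log2fc,
            dispersion=config.dispersion,
            seed=config.seed,
            samples=samples,
        )
        genotypes = genotypes_full.subset([s.sample_id for s in samples])
        hio.write_genotypes(genotypes_full, out / "genotypes.tsv")
        hio.write_counts(counts, out / "counts.tsv")
        hio.write_samples(samples, out / "samples.tsv")
        (out / "truth_genotypes.json").write_text(truth_g.to_json() + "\n")
        (out / "truth_counts.json").write_text(truth_c.to_json() + "\n")
        for name in ("genotypes.tsv", "counts.tsv", "samples.tsv", "truth_genotypes.json", "truth_counts.json"):
            emit(name, out / name)
    else:
        if config.genotypes_path:
            genotypes = hio.read_genotypes(config.genotypes_path)
        if config.counts_path:
            counts = hio.read_counts(config.counts_path)
        if config.samples_path:
            samples = hio.read_samples(config.samples_path)

    rpkm = None
    if "prep" in config.stages:
        if counts is None:
            raise ValueError("stage 'prep' needs a count table (simulate or counts_path)")
        kept = filter_low_expression(counts, config.min_expressing_fish, config.min_total_cpm)
        counts = counts.subset(kept)
        rpkm = compute_rpkm(counts)
        high = high_expression_subset(rpkm, config.min_rpkm, config.min_fish)
        hio.write_json(
            {"kept_contigs": kept, "high_expression_contigs": high}, out / "prep_filters.json"
        )
        emit("prep_filters.json", out / "prep_filters.json")
        manifest["results"]["prep"] = {"n_kept": len(kept), "n_high_expression": len(high)}

    if "kinship" in config.stages:
        if genotypes is None:
            raise ValueError("stage 'kinship' needs genotypes (simulate or genotypes_path)")
        matrix = cssc_distance_matrix(genotypes)
        hio.write_matrix(matrix, out / "cssc_distance.tsv")
        tree = neighbor_joining(matrix)
        (out / "cssc_tree.nwk").write_text(write_newick(tree) + "\n")
        emit("cssc_distance.tsv", out / "cssc_distance.tsv")
        emit("cssc_tree.nwk", out / "cssc_tree.nwk")

    if "pad" in config.stages:
        if counts is None:
            raise ValueError("stage 'pad' needs a count table (simulate or counts_path)")
        if rpkm is None:
            rpkm = compute_rpkm(counts)
        expr = rpkm
        if config.pad_high_expression_only:
            high = high_expression_subset(rpkm, config.min_rpkm, config.min_fish)
            if not high:
                raise ValueError("high-expression subset is empty; cannot compute PAD")
            expr = compute_rpkm(counts.subset(high))
        ratios, excluded = median_ratio_adjust(expr, transform=config.pad_transform)
        matrix = pad_matrix(ratios)
        hio.write_matrix(matrix, out / "pad_distance.tsv")
        (out / "pad_excluded.tsv").write_text("\n".join(["contig_id", *excluded]) + "\n")
        tree = neighbor_joining(matrix)
        (out / "pad_tree.nwk").write_text(write_newick(tree) + "\n")
        for name in ("pad_distance.tsv", "pad_excluded.tsv", "pad_tree.nwk"):
            emit(name, out / name)
        manifest["results"]["pad"] = {"n_excluded_median_zero": len(excluded), "transform": config.pad_transform}

    if "discan" in config.stages:
        if genotypes is None or samples is None:
            raise ValueError("stage 'discan' needs genotypes and sample records")
        records = scan_size_markers(
            genotypes, samples, config.di_threshold, config.min_informative, config.di_criterion
        )
        lines = ["marker_id\t" + "\t".join(
            f"di_{l}\tn_informative_{l}" for l in sorted({s.lot.value for s in samples})
        ) + "\tpasses"]
        for r in records:
            parts = [r.marker_id]
            for l in sorted(r.di_by_lot):
                parts += [f"{r.di_by_lot[l]:.6f}", str(r.n_informative_by_lot[l])]
            parts.append("1")
            lines.append("\t".join(parts))
        (out / "di_passing.tsv").write_text("\n".join(lines) + "\n")
        emit("di_passing.tsv", out / "di_passing.tsv")
        summary = {
            "threshold": config.di_threshold,
            "criterion": config.di_criterion,
            "n_passing": len(records),
            "seed": config.seed,
        }
        if config.n_perm > 0:
            null = permutation_null(
                genotypes,
                samples,
                n_perm=config.n_perm,
                threshold=config.di_threshold,
                seed=config.seed,
                min_informative=config.min_informative,
                criterion=config.di_criterion,
            )
            summary["permutation"] = {
                "n_perm": null.n_perm,
                "observed": null.observed,
                "p_value": null.p_value,
                "null_quantiles": {
                    q: null.quantile(float(q)) for q in ("0.025", "0.5", "0.975")
                },
            }
        hio.write_json(summary, out / "di_scan_summary.json")
        emit("di_scan_summary.json", out / "di_scan_summary.json")
        manifest["results"]["discan"] = summary

    if "overlap" in config.stages:
        if not config.overlap_counts or len(config.overlap_counts) != 4:
            raise ValueError("stage 'overlap' needs overlap_counts = [sept_small, dec_small, sept_large, dec_large]")
        table = overlap_2x2(*config.overlap_counts)
        res = chi_square_2x2(table)
        hio.write_json(res.to_dict(), out / "overlap_chi2.json")
        emit("overlap_chi2.json", out / "overlap_chi2.json")
        manifest["results"]["overlap"] = res.to_dict()

    if "gotest" in config.stages:
        if not config.gotest_counts:
            raise ValueError("stage 'gotest' needs gotest_counts (2 x k)")
        table = ContingencyTable2xK(
            np.asarray(config.gotest_counts), category_labels=config.gotest_categories
        )
        res = g_test(table, williams=config.williams)
        trace = backward_elimination_g(table, alpha=config.alpha, williams=config.williams)
        hio.write_json({"g_test": res.to_dict(), "elimination": trace.to_dict()}, out / "gotest.json")
        emit("gotest.json", out / "gotest.json")
        manifest["results"]["gotest"] = {"g": res.value, "p": res.p_value, "flagged": trace.flagged}

    hio.write_json(manifest, out / "manifest.json")
    return manifest
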