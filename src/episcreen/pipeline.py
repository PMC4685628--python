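"""End-to-end screen assembly: simulate/load -> QC -> tagging -> association
-> pairwise MDR -> report tables.

Every random stage takes an explicit seed derived from the run config, so a
run is fully reproducible: the same config produces byte-identical output
files (timestamps go to the stderr log only, never into outputs).
"""

from __future__ import annotations

import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .association import AssociationResult, AssocSummary, associate_all, qq_lambda
from .dataset import GenotypeDataset
from .io import read_gene_annotation, read_plink_text, read_tsv_matrix
from .mdr import MDRConfig, MDRModel, ScanResult, scan_pairs, significance_filter
from .qc import QCReport, QCThresholds, apply_qc
from .simulate import SimConfig, TruthRecord, simulate_cohort
from .tagging import TagSet, greedy_tag_selection


@dataclass
class PipelineConfig:
    """One screen run: input source, stage settings, seeds."""

    sim: Optional[SimConfig] = None
    ped_path: Optional[str] = None
    map_path: Optional[str] = None
    matrix_path: Optional[str] = None
    samples_path: Optional[str] = None
    variants_path: Optional[str] = None
    annotation_path: Optional[str] = None
    qc: QCThresholds = field(default_factory=QCThresholds)
    r2_threshold: float = 0.8
    window_bp: int = 250_000
    mdr: MDRConfig = field(default_factory=MDRConfig)
    genes_only: bool = True  # restrict the pair universe to gene-mapped tags
    workers: int = 1

    def __post_init__(self) -> None:
        sources = [
            self.sim is not None,
            self.ped_path is not None,
            self.matrix_path is not None,
        ]
        if sum(sources) != 1:
            raise ValueError(
                "exactly one input source required: sim config, .ped/.map, "
                "or TSV matrix"
            )


@dataclass
class PipelineRun:
    """Snapshot of one complete run: config, stage outputs, provenance."""

    config: PipelineConfig
    dataset: GenotypeDataset  # post-QC
    truth: Optional[TruthRecord]
    qc_report: QCReport
    tagset: TagSet
    association: list[AssociationResult]
    assoc_summary: Optional[AssocSummary]
    scan: ScanResult
    significant: list[MDRModel]
    version: str = __version__


def _log(stage: str, t0: float) -> None:
    print(f"[episcreen] {stage}: {time.perf_counter() - t0:.2f}s", file=sys.stderr)


def _load_dataset(config: PipelineConfig) -> tuple[GenotypeDataset, Optional[TruthRecord]]:
    if config.sim is not None:
        return simulate_cohort(config.sim)
    if config.ped_path is not None:
        if config.map_path is None:
            raise ValueError("ped input requires map_path")
        return read_plink_text(config.ped_path, config.map_path), None
    return (
        read_tsv_matrix(config.matrix_path, config.samples_path, config.variants_path),
        None,
    )


def run_pipeline(config: PipelineConfig) -> PipelineRun:
    """Execute the full screen; any stage error propagates with its name."""
    t0 = time.perf_counter()
    try:
        ds, truth = _load_dataset(config)
    except Exception as exc:
        raise RuntimeError(f"stage 'load': {exc}") from exc
    _log("load", t0)

    if config.annotation_path is not None:
        gene_map = read_gene_annotation(config.annotation_path, ds.variants)
        ds = ds.with_genes(gene_map)

    t = time.perf_counter()
    try:
        ds_qc, qc_report = apply_qc(ds, config.qc)
    except Exception as exc:
        raise RuntimeError(f"stage 'qc': {exc}") from exc
    _log("qc", t)

    t = time.perf_counter()
    try:
        tagset = greedy_tag_selection(ds_qc, config.r2_threshold, config.window_bp)
    except Exception as exc:
        raise RuntimeError(f"stage 'tag': {exc}") from exc
    _log("tag", t)

    t = time.perf_counter()
    try:
        association = associate_all(ds_qc)
        assoc_summary = (
            qq_lambda(
                [r.p_nominal for r in association],
                positions=pd.DataFrame(
                    {
                        "chrom": [v.chrom for v in ds_qc.variants],
                        "pos": [v.pos for v in ds_qc.variants],
                    }
                ),
            )
            if len(association) >= 10
            else None
        )
    except Exception as exc:
        raise RuntimeError(f"stage 'assoc': {exc}") from exc
    _log("assoc", t)

    t = time.perf_counter()
    try:
        tag_ids = set(tagset.tags)
        gene_of = {v.id: v.gene for v in ds_qc.variants}
        universe_ids = [
            vid
            for vid in ds_qc.variant_ids
            if vid in tag_ids
            and (not config.genes_only or gene_of[vid] is not None)
        ]
        if config.genes_only and not universe_ids:
            # no gene annotation supplied: fall back to all tag SNPs
            universe_ids = [vid for vid in ds_qc.variant_ids if vid in tag_ids]
        from .mdr import all_pairs

        scan = scan_pairs(
            ds_qc.subset(
                variant_idx=[ds_qc.variant_index(v) for v in universe_ids]
            ),
            pairs=all_pairs(universe_ids),
            config=config.mdr,
            workers=config.workers,
        )
    except Exception as exc:
        raise RuntimeError(f"stage 'mdr': {exc}") from exc
    _log("mdr", t)

    significant = significance_filter(scan.models, config.mdr.cvv_threshold)
    return PipelineRun(
        config=config,
        dataset=ds_qc,
        truth=truth,
        qc_report=qc_report,
        tagset=tagset,
        association=association,
        assoc_summary=assoc_summary,
        scan=scan,
        significant=significant,
    )


# ---------------------------------------------------------------------------
# report rendering
# ---------------------------------------------------------------------------


def render_interaction_table(models: list[MDRModel]) -> pd.DataFrame:
    """Gene-gene interaction table: SNP1, SNP2, gene1, gene2, CVV (3 dp)."""
    rows = [
        {
            "SNP1": m.id1,
            "SNP2": m.id2,
            "gene1": m.gene1 if m.gene1 is not None else "NA",
            "gene2": m.gene2 if m.gene2 is not None else "NA",
            "CVV": f"{m.cvv:.3f}",
            "significant": str(bool(m.significant)).lower(),
        }
        for m in models
    ]
    return pd.DataFrame(
        rows, columns=["SNP1", "SNP2", "gene1", "gene2", "CVV", "significant"]
    )


def render_snp_table(results: list[AssociationResult]) -> pd.DataFrame:
    """Per-SNP association table mirroring the interaction-SNP summary layout."""
    rows = [
        {
            "SNP": r.variant_id,
            "gene": r.gene if r.gene is not None else "NA",
            "freq_cases": f"{r.freq_cases:.4f}",
            "freq_controls": f"{r.freq_controls:.4f}",
            "OR": f"{r.odds_ratio:.4g}",
            "ci_low": f"{r.ci95[0]:.4g}",
            "ci_high": f"{r.ci95[1]:.4g}",
            "p": f"{r.p_nominal:.4g}",
            "p_adjusted": f"{r.p_adjusted:.4g}",
        }
        for r in results
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "SNP",
            "gene",
            "freq_cases",
            "freq_controls",
            "OR",
            "ci_low",
            "ci_high",
            "p",
            "p_adjusted",
        ],
    )


def write_run(run: PipelineRun, outdir: str) -> dict[str, Path]:
    """Write all run outputs (TSV tables + QC report) into ``outdir``.

    Deterministic: identical config + seeds give byte-identical files.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    run.qc_report.write(str(out / "run"))
    paths["qc_samples"] = out / "run.qc_samples.tsv"
    paths["qc_variants"] = out / "run.qc_variants.tsv"
    paths["qc_summary"] = out / "run.qc_summary.txt"

    tags_path = out / "tags.tsv"
    run.tagset.write(str(tags_path))
    paths["tags"] = tags_path

    assoc_path = out / "association.tsv"
    render_snp_table(run.association).to_csv(assoc_path, sep="\t", index=False)
    paths["association"] = assoc_path

    inter_path = out / "interactions.tsv"
    render_interaction_table(run.scan.models).to_csv(inter_path, sep="\t", index=False)
    paths["interactions"] = inter_path

    sig_path = out / "interactions_significant.tsv"
    render_interaction_table(run.significant).to_csv(sig_path, sep="\t", index=False)
    paths["significant"] = sig_path

    # SNPs involved in significant interactions, with association statistics
    sig_ids = sorted({i for m in run.significant for i in (m.id1, m.id2)})
    sig_assoc = [r for r in run.association if r.variant_id in sig_ids]
    snp_path = out / "significant_snps.tsv"
    render_snp_table(sig_assoc).to_csv(snp_path, sep="\t", index=False)
    paths["significant_snps"] = snp_path

    prov_path = out / "provenance.txt"
    with open(prov_path, "w") as fh:
        fh.write(f"episcreen version\t{run.version}\n")
        fh.write(f"samples_post_qc\t{run.dataset.n_samples}\n")
        fh.write(f"variants_post_qc\t{run.dataset.n_variants}\n")
        fh.write(f"tags\t{run.tagset.n_tags}\n")
        fh.write(f"pairs_scanned\t{len(run.scan.table)}\n")
        if run.assoc_summary is not None:
            fh.write(f"lambda_gc\t{run.assoc_summary.lambda_gc:.4f}\n")
        fh.write(f"qc_summary\t{run.qc_report.summary()}\n")
    paths["provenance"] = prov_path
    return paths
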