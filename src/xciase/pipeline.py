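"""End-to-end orchestration: simulate -> AE -> screen -> classify -> curate.

One :class:`PipelineConfig` carries every tunable constant (filter
thresholds, the 0.475 screen cutoff, the 0.025 binomial null, the 0.01 q
cutoff, curation parameters, seeds) and is echoed, fully resolved, into
the output directory so every run is self-describing.  Stage boundaries
log record counts, making filter attrition auditable.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from . import ase, classify, curate, screen, simulate
from .io import (
    GeneAnnotation,
    ParIntervals,
    read_allele_count_table,
    read_gene_annotations,
    read_het_snp_table,
)

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """The pipeline configuration is invalid."""


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs, serialisable to/from YAML."""

    outdir: str = "xciase_out"
    # inputs (ignored when simulate is set)
    counts_path: str | None = None
    genotype_vcfs: dict[str, str] = field(default_factory=dict)  # assay -> path
    genes_path: str | None = None
    # simulation
    simulate: dict[str, Any] | None = None
    # thresholds
    screen_threshold: float = screen.SCREEN_THRESHOLD
    null_p: float = classify.NULL_XI_FRACTION
    q_threshold: float = classify.Q_THRESHOLD
    min_screen_genes: int = 10
    screen_filters: dict[str, Any] = field(default_factory=dict)
    detailed_filters: dict[str, Any] = field(default_factory=dict)
    curation: dict[str, Any] = field(default_factory=dict)
    sample_exclusions: list[list[str]] = field(default_factory=list)  # [donor, tissue]
    outlier_rule: bool = False
    par_contig: str = "chrX"
    par1: tuple[int, int] = ParIntervals.par1
    par2: tuple[int, int] = ParIntervals.par2
    seed: int = 0
    bootstrap_resamples: int = 1000

    def __post_init__(self) -> None:
        if not 0.0 < self.screen_threshold < 0.5:
            raise ConfigError("screen_threshold must lie in (0, 0.5)")
        if not 0.0 < self.null_p < 1.0:
            raise ConfigError("null_p must lie in (0, 1)")
        if not 0.0 < self.q_threshold <= 1.0:
            raise ConfigError("q_threshold must lie in (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        for key in ("par1", "par2"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["par1"] = list(data["par1"])
        data["par2"] = list(data["par2"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    def par_intervals(self) -> ParIntervals:
        return ParIntervals(contig=self.par_contig, par1=tuple(self.par1),
                            par2=tuple(self.par2))


def _load_inputs(config: PipelineConfig, outdir: Path):
    """Simulate or read the genotype, count and annotation inputs."""
    if config.simulate is not None:
        sim_kwargs = dict(config.simulate)
        sim_kwargs.setdefault("seed", config.seed)
        sim_config = simulate.SimConfig(**sim_kwargs)
        sim = simulate.simulate_dataset(sim_config)
        inputs_dir = outdir / "inputs"
        sim.write(inputs_dir)
        logger.info("simulated %d donors, %d count rows -> %s",
                    sim_config.n_donors, len(sim.counts), inputs_dir)
        return sim.counts, sim.genotypes, sim.annotations
    if not (config.counts_path and config.genotype_vcfs and config.genes_path):
        raise ConfigError("either `simulate` or counts_path + genotype_vcfs + "
                          "genes_path must be configured")
    counts = read_allele_count_table(config.counts_path)
    geno_frames = [
        read_het_snp_table(path, assay=assay, contig=config.par_contig)
        for assay, path in sorted(config.genotype_vcfs.items())
    ]
    genotypes = pd.concat(geno_frames, ignore_index=True)
    annotations = read_gene_annotations(config.genes_path, config.par_intervals())
    return counts, genotypes, annotations


def _designated_screen_samples(counts: pd.DataFrame) -> pd.DataFrame:
    """One designated sample per donor: the first in sorted sample order."""
    designated = counts[["donor", "sample"]].drop_duplicates().sort_values(
        ["donor", "sample"]).drop_duplicates("donor")
    return counts.merge(designated, on=["donor", "sample"], how="inner")


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run every stage and write all tables under ``config.outdir``.

    Returns a summary dict (also written as ``summary.txt``) with
    per-stage record counts, the nmXCI verdicts, the consensus status
    tallies before and after curation, and the variable-gene fraction.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts, genotypes, annotations = _load_inputs(config, outdir)
    config.to_yaml(outdir / "config_resolved.yaml")
    summary: dict[str, Any] = {"n_count_rows": int(len(counts)),
                               "n_genotype_rows": int(len(genotypes))}

    # --- screen ---
    screen_policy = ase.FilterPolicy.screen(**config.screen_filters)
    screen_counts = _designated_screen_samples(counts)
    screen_ae = ase.compute_ae_table(screen_counts, genotypes, annotations, screen_policy)
    screen_ae.to_csv(outdir / "screen_ae.tsv", sep="\t", index=False)
    cohort = screen.screen_cohort(screen_ae, threshold=config.screen_threshold,
                                  min_genes=config.min_screen_genes,
                                  n_boot=config.bootstrap_resamples, seed=config.seed)
    cohort.to_csv(outdir / "screen_cohort.tsv", sep="\t", index=False)
    nmxci_donors = sorted(cohort.loc[cohort["verdict"] == "nmXCI", "donor"])
    summary["n_screened"] = int(len(cohort))
    summary["n_nmxci"] = len(nmxci_donors)
    summary["nmxci_donors"] = nmxci_donors
    logger.info("screen verdicts: %d nmXCI of %d donors", len(nmxci_donors), len(cohort))
    if not nmxci_donors:
        summary["note"] = "no nmXCI donors detected; classification skipped"
        _write_summary(summary, outdir)
        return summary

    # --- detailed AE on nmXCI donors ---
    detailed_policy = ase.FilterPolicy.detailed(**config.detailed_filters)
    detailed_counts = counts[counts["donor"].isin(nmxci_donors)].reset_index(drop=True)
    detailed_ae = ase.compute_ae_table(detailed_counts, genotypes, annotations,
                                       detailed_policy, with_xi=True)
    exclusions = [tuple(pair) for pair in config.sample_exclusions]
    detailed_ae, exclusion_log = ase.exclude_flagged_samples(
        detailed_ae, exclusions, outlier_rule=config.outlier_rule)
    detailed_ae.to_csv(outdir / "detailed_ae.tsv", sep="\t", index=False)
    exclusion_log.to_csv(outdir / "sample_exclusions.tsv", sep="\t", index=False)
    summary["n_detailed_rows"] = int(len(detailed_ae))
    summary["n_samples_excluded"] = int(len(exclusion_log))

    confirmations = []
    for donor in nmxci_donors:
        calls, confirmed = screen.confirm_multi_tissue(
            detailed_ae[detailed_ae["donor"] == donor],
            threshold=config.screen_threshold, min_genes=config.min_screen_genes,
            n_boot=config.bootstrap_resamples, seed=config.seed)
        calls = calls.assign(confirmed=confirmed)
        confirmations.append(calls)
    confirmation = pd.concat(confirmations, ignore_index=True)
    confirmation.to_csv(outdir / "nmxci_confirmation.tsv", sep="\t", index=False)
    confirmed_donors = sorted(confirmation.loc[confirmation["confirmed"], "donor"].unique())
    summary["confirmed_nmxci_donors"] = confirmed_donors

    # --- classification ---
    classify_ae = detailed_ae[detailed_ae["donor"].isin(confirmed_donors)]
    escape_calls = classify.escape_call_table(classify_ae, null_p=config.null_p,
                                              q_threshold=config.q_threshold)
    escape_calls.to_csv(outdir / "escape_calls.tsv", sep="\t", index=False)
    per_donor, consensus = classify.classify_genes(escape_calls)
    per_donor.to_csv(outdir / "status_per_donor.tsv", sep="\t", index=False)
    consensus.to_csv(outdir / "consensus.tsv", sep="\t", index=False)
    summary["n_genes_classified"] = int(len(consensus))
    summary["status_tally"] = consensus["consensusStatus"].value_counts().to_dict()

    # --- curation ---
    params = curate.CurationParams(**config.curation) if config.curation else curate.CurationParams()
    curated, audit = curate.curate_all(consensus, escape_calls, params)
    curated.to_csv(outdir / "consensus_curated.tsv", sep="\t", index=False)
    audit.to_csv(outdir / "curation_audit.tsv", sep="\t", index=False)
    summary["n_genes_recurated"] = int(audit["changed"].sum())
    summary["curated_status_tally"] = curated["consensusStatus"].value_counts().to_dict()
    var_frac = classify.variable_fraction(curated["consensusStatus"])
    summary["variable_fraction_percent"] = var_frac

    matrix = render_matrix(curated, escape_calls)
    matrix.to_csv(outdir / "ae_matrix.tsv", sep="\t")
    _write_summary(summary, outdir)
    return summary


def _write_summary(summary: dict[str, Any], outdir: Path) -> None:
    lines = []
    for key, value in summary.items():
        if key == "variable_fraction_percent":
            lines.append(f"variable: {value}%")
        else:
            lines.append(f"{key}: {value}")
    (outdir / "summary.txt").write_text("\n".join(lines) + "\n")


def render_matrix(consensus: pd.DataFrame, escape_calls: pd.DataFrame,
                  include_all: bool = False) -> pd.DataFrame:
    """Gene x tissue AE matrix with escape markers and a consensus column.

    Cells hold the AE value (averaged over donors when several cover the
    tissue) with a ``*`` marker when Xi expression is significant; missing
    data is ``NA`` — distinguishable from a measured non-escape cell.  By
    default only escape-type and variable genes are shown, mirroring a
    constitutive-or-variable-escape heatmap; ``include_all`` keeps every
    classified gene.
    """
    keep = consensus if include_all else consensus[
        consensus["consensusStatus"].isin([classify.ESCAPE, classify.ESCAPE_SINGLE,
                                           classify.VARIABLE])]
    genes = list(keep["geneId"])
    status = dict(zip(keep["geneId"], keep["consensusStatus"]))
    tissues = sorted(escape_calls["tissue"].unique()) if not escape_calls.empty else []
    rows = {}
    calls = escape_calls[escape_calls["geneId"].isin(genes)]
    grouped = calls.groupby(["geneId", "tissue"])
    agg = grouped.agg(ae=("aeValue", "mean"), sig=("escape", "any"))
    for gene in genes:
        row = {}
        for tissue in tissues:
            try:
                cell = agg.loc[(gene, tissue)]
            except KeyError:
                row[tissue] = "NA"
                continue
            row[tissue] = f"{cell['ae']:.3f}{'*' if cell['sig'] else ''}"
        row["consensusCall"] = status[gene]
        rows[gene] = row
    matrix = pd.DataFrame.from_dict(rows, orient="index",
                                    columns=tissues + ["consensusCall"])
    matrix.index.name = "geneId"
    return matrix
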