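"""Filtered per-gene, per-tissue allelic expression from hetSNP counts.

The allelic expression (AE) of a hetSNP is ``abs(0.5 - ref/(ref+alt))``:
0 means complete biallelic expression, 0.5 complete monoallelic
expression.  This module turns raw allele-count tables into one AE value
per gene, tissue and donor by

1. keeping only hetSNPs whose genotype call is well supported
   (:func:`apply_genotype_filters`),
2. merging sites contributed by both the WES- and WGS-derived site lists,
   keeping the record with the larger total count
   (:func:`merge_assay_counts`),
3. requiring a minimal RNA read depth (:func:`apply_rna_filters`),
4. choosing one representative hetSNP per gene
   (:func:`select_snp_per_gene`),

in either ``screen`` mode (the cohort-wide nmXCI screen: strict genotype
depth >= 20 per allele on WES, RNA depth > 10) or ``detailed`` mode (the
per-donor multi-tissue analysis: depth >= 10 per allele on the
contributing assay, RNA depth > 7).  A donor-fixed inactive-X (Xi) allele
per SNP is assigned by :func:`assign_xi_allele` for the downstream escape
test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import GeneAnnotation, HetSnpGenotype, SnpKey, ValidationError

logger = logging.getLogger(__name__)

Mode = Literal["screen", "detailed"]

#: Column layout of the gene x tissue AE table.
AE_COLUMNS = [
    "donor", "sample", "tissue", "geneId", "parRegion", "priorStatus",
    "contig", "position", "refAllele", "altAllele",
    "refCount", "altCount", "usedDepth", "aeValue",
]
XI_COLUMNS = ["xiAllele", "xiCount", "xiFraction"]


@dataclass(frozen=True)
class FilterPolicy:
    """Site-quality thresholds for one analysis mode.

    Inequalities are deliberately mixed: genotype depth is inclusive
    (``>=``), the minor-allele genotype fraction and the RNA depth are
    strict (``>``).
    """

    mode: Mode
    min_genotype_depth_per_allele: int
    min_minor_fraction_genotype: float = 0.10
    min_rna_depth: int = 10  # strict: keep records with ref+alt > this

    @classmethod
    def screen(cls, **overrides) -> "FilterPolicy":
        defaults = dict(mode="screen", min_genotype_depth_per_allele=20, min_rna_depth=10)
        defaults.update(overrides)
        return cls(**defaults)

    @classmethod
    def detailed(cls, **overrides) -> "FilterPolicy":
        defaults = dict(mode="detailed", min_genotype_depth_per_allele=10, min_rna_depth=7)
        defaults.update(overrides)
        return cls(**defaults)


def compute_ae(ref_count: int, alt_count: int) -> float:
    """Allelic expression ``abs(0.5 - ref/(ref+alt))``.

    Symmetric in its arguments; 0 for balanced biallelic expression and
    0.5 for monoallelic expression.  A zero total is undefined.  Evaluated
    as ``|ref - alt| / (2 * (ref + alt))``, the algebraically identical
    form that is exactly symmetric in floating point.
    """
    total = ref_count + alt_count
    if total <= 0:
        raise ValidationError("compute_ae is undefined for zero total count")
    return abs(ref_count - alt_count) / (2 * total)


def ae_values(ref_counts: np.ndarray, alt_counts: np.ndarray) -> np.ndarray:
    """Vectorised :func:`compute_ae`."""
    ref = np.asarray(ref_counts)
    alt = np.asarray(alt_counts)
    total = ref + alt
    if (total <= 0).any():
        raise ValidationError("compute_ae is undefined for zero total count")
    return np.abs(ref - alt) / (2 * total)


# ---------------------------------------------------------------------------
# Genotype-level filtering
# ---------------------------------------------------------------------------

def apply_genotype_filters(
    genotypes: Iterable[HetSnpGenotype] | pd.DataFrame,
    policy: FilterPolicy,
) -> set[SnpKey]:
    """Sites whose genotype call survives the depth and balance filters.

    A site survives if, on an eligible assay, both allele depths are
    ``>= min_genotype_depth_per_allele`` and the minor allele depth exceeds
    ``min_minor_fraction_genotype`` of the total.  Screen mode considers
    WES genotypes only (the screen was run off the released exome VCF);
    detailed mode considers whichever assay supplied the site.
    """
    frame = _genotype_frame(genotypes)
    frame = _surviving_genotypes(frame, policy)
    return {
        SnpKey(r.contig, int(r.position), r.ref, r.alt)
        for r in frame.itertuples(index=False)
    }


def _genotype_frame(genotypes: Iterable[HetSnpGenotype] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(genotypes, pd.DataFrame):
        return genotypes
    rows = [
        (g.donor, g.key.contig, g.key.position, g.key.ref, g.key.alt, g.assay,
         g.ref_depth, g.alt_depth, g.passed_variant_filter)
        for g in genotypes
    ]
    return pd.DataFrame(rows, columns=["donor", "contig", "position", "ref", "alt",
                                       "assay", "refDepth", "altDepth", "passedVariantFilter"])


def _surviving_genotypes(frame: pd.DataFrame, policy: FilterPolicy) -> pd.DataFrame:
    if frame.empty:
        return frame
    if policy.mode == "screen":
        frame = frame[frame["assay"] == "WES"]
    rd = frame["refDepth"].to_numpy()
    ad = frame["altDepth"].to_numpy()
    total = rd + ad
    minor = np.minimum(rd, ad)
    keep = (
        frame["passedVariantFilter"].to_numpy()
        & (rd >= policy.min_genotype_depth_per_allele)
        & (ad >= policy.min_genotype_depth_per_allele)
        & (total > 0)
    )
    keep &= np.divide(minor, np.maximum(total, 1)) > policy.min_minor_fraction_genotype
    return frame[keep]


def filter_counts_by_genotype(
    counts: pd.DataFrame,
    genotypes: pd.DataFrame,
    policy: FilterPolicy,
) -> pd.DataFrame:
    """Keep allele-count rows whose (donor, site, assay) genotype survives.

    Each count row is matched to the genotype of the assay that supplied
    it; in screen mode only WES-derived rows can survive.
    """
    if counts.empty:
        return counts
    surviving = _surviving_genotypes(genotypes, policy)
    key_cols_geno = ["donor", "contig", "position", "ref", "alt", "assay"]
    keys = set(map(tuple, surviving[key_cols_geno].itertuples(index=False, name=None)))
    count_keys = counts[["donor", "contig", "position", "refAllele", "altAllele", "assay"]]
    mask = [tuple(row) in keys for row in count_keys.itertuples(index=False, name=None)]
    return counts[np.asarray(mask, dtype=bool)].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Assay merging and RNA filtering
# ---------------------------------------------------------------------------

def merge_assay_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Collapse duplicate sites contributed by both genotype pipelines.

    For a site present from both the WES- and WGS-derived site lists in
    the same sample, the record with the larger ``totalCount`` is kept;
    exact ties go to WGS (PCR-free, hence the less biased source).  Sites
    present once pass through unchanged.  Conflicting ref/alt alleles at
    the same coordinate are a data inconsistency.
    """
    if counts.empty:
        return counts
    site_cols = ["donor", "sample", "contig", "position"]
    allele_check = counts.groupby(site_cols)[["refAllele", "altAllele"]].nunique()
    bad = allele_check[(allele_check > 1).any(axis=1)]
    if len(bad):
        first = bad.index[0]
        raise ValidationError(f"conflicting ref/alt alleles at {first[2]}:{first[3]} "
                              f"for sample {first[1]}")
    ranked = counts.assign(_wgs=(counts["assay"] == "WGS").astype(int))
    ranked = ranked.sort_values(["totalCount", "_wgs"], ascending=[False, False], kind="stable")
    merged = ranked.drop_duplicates(subset=site_cols, keep="first").drop(columns="_wgs")
    return merged.sort_values(["donor", "sample", "contig", "position"],
                              kind="stable").reset_index(drop=True)


def apply_rna_filters(counts: pd.DataFrame, policy: FilterPolicy) -> pd.DataFrame:
    """Keep rows with biallelic RNA depth strictly above the threshold.

    "RNA read depth" is ``refCount + altCount`` — the two genotype alleles
    only; reads carrying other bases are likely errors and are ignored.
    """
    if counts.empty:
        return counts
    depth = counts["refCount"] + counts["altCount"]
    return counts[depth > policy.min_rna_depth].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Gene mapping and SNP selection
# ---------------------------------------------------------------------------

def map_counts_to_genes(counts: pd.DataFrame,
                        annotations: Sequence[GeneAnnotation]) -> pd.DataFrame:
    """Attach geneId / parRegion / priorStatus by interval overlap.

    A SNP inside several overlapping genes yields one row per gene; SNPs
    outside every gene are dropped.
    """
    if counts.empty:
        out = counts.copy()
        for col in ("geneId", "parRegion", "priorStatus"):
            out[col] = pd.Series(dtype=object)
        return out
    gene_frame = pd.DataFrame([
        (g.contig, g.start, g.end, g.gene_id, g.par_region, g.prior_status)
        for g in annotations
    ], columns=["contig", "start", "end", "geneId", "parRegion", "priorStatus"])
    pieces = []
    for contig, group in counts.groupby("contig", sort=False):
        genes_here = gene_frame[gene_frame["contig"] == contig]
        if genes_here.empty:
            continue
        starts = genes_here["start"].to_numpy()
        ends = genes_here["end"].to_numpy()
        pos = group["position"].to_numpy()
        hit_snp, hit_gene = np.nonzero((pos[:, None] >= starts[None, :])
                                       & (pos[:, None] <= ends[None, :]))
        if hit_snp.size == 0:
            continue
        piece = group.iloc[hit_snp].reset_index(drop=True)
        ann = genes_here.iloc[hit_gene][["geneId", "parRegion", "priorStatus"]].reset_index(drop=True)
        pieces.append(pd.concat([piece, ann], axis=1))
    if not pieces:
        out = counts.iloc[0:0].copy()
        for col in ("geneId", "parRegion", "priorStatus"):
            out[col] = pd.Series(dtype=object)
        return out
    return pd.concat(pieces, ignore_index=True)


def select_snp_per_gene(counts: pd.DataFrame, mode: Mode) -> pd.DataFrame:
    """Reduce each gene to a single representative hetSNP.

    screen mode — per gene and sample, the SNP with the highest RNA read
    count wins.  detailed mode — per gene and donor, the SNP surviving
    filters in the most tissues wins; ties go to the highest summed RNA
    read count, then to the lowest genomic coordinate (for determinism).
    """
    if counts.empty:
        return counts
    counts = counts.assign(_depth=counts["refCount"] + counts["altCount"])
    if mode == "screen":
        ranked = counts.sort_values(["_depth", "position"], ascending=[False, True], kind="stable")
        out = ranked.drop_duplicates(subset=["donor", "sample", "geneId"], keep="first")
        return out.drop(columns="_depth").reset_index(drop=True)

    snp_cols = ["donor", "geneId", "contig", "position", "refAllele", "altAllele"]
    stats = (counts.groupby(snp_cols, as_index=False)
             .agg(nTissues=("tissue", "nunique"), sumDepth=("_depth", "sum")))
    stats = stats.sort_values(["nTissues", "sumDepth", "position"],
                              ascending=[False, False, True], kind="stable")
    winners = stats.drop_duplicates(subset=["donor", "geneId"], keep="first")[snp_cols]
    out = counts.merge(winners, on=snp_cols, how="inner")
    return out.drop(columns="_depth").reset_index(drop=True)


def build_ae_frame(selected: pd.DataFrame) -> pd.DataFrame:
    """Attach usedDepth and the AE statistic to selected count rows."""
    if selected.empty:
        return pd.DataFrame(columns=AE_COLUMNS)
    out = selected.copy()
    out["usedDepth"] = out["refCount"] + out["altCount"]
    out["aeValue"] = ae_values(out["refCount"].to_numpy(), out["altCount"].to_numpy())
    return out[AE_COLUMNS].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Xi-allele assignment (nmXCI donors only)
# ---------------------------------------------------------------------------

def assign_xi_allele(donor_counts: pd.DataFrame) -> pd.DataFrame:
    """Assign each donor-SNP its inactive-X allele, fixed across tissues.

    The Xi allele is the allele with the smaller read count summed over
    all the donor's tissues — in an nmXCI female the minor allele is the
    Xi haplotype genome-wide.  Exact ties go to the alt allele with a
    warning.  Returns one row per (donor, contig, position, refAllele,
    altAllele) with column ``xiAllele`` in {'ref', 'alt'}.
    """
    site_cols = ["donor", "contig", "position", "refAllele", "altAllele"]
    sums = donor_counts.groupby(site_cols, as_index=False)[["refCount", "altCount"]].sum()
    ties = sums["refCount"] == sums["altCount"]
    if ties.any():
        for row in sums[ties].itertuples(index=False):
            logger.warning("Xi-allele tie at %s:%d for donor %s; choosing alt",
                           row.contig, row.position, row.donor)
    sums["xiAllele"] = np.where(sums["refCount"] < sums["altCount"], "ref", "alt")
    return sums[site_cols + ["xiAllele"]]


def add_xi_columns(ae_frame: pd.DataFrame) -> pd.DataFrame:
    """Add xiAllele / xiCount / xiFraction columns to an AE frame."""
    if ae_frame.empty:
        out = ae_frame.copy()
        for col in XI_COLUMNS:
            out[col] = pd.Series(dtype=float if col != "xiAllele" else object)
        return out
    assignment = assign_xi_allele(ae_frame)
    out = ae_frame.merge(assignment,
                         on=["donor", "contig", "position", "refAllele", "altAllele"],
                         how="left")
    is_ref = out["xiAllele"] == "ref"
    out["xiCount"] = np.where(is_ref, out["refCount"], out["altCount"]).astype(int)
    out["xiFraction"] = out["xiCount"] / out["usedDepth"]
    return out


# ---------------------------------------------------------------------------
# Sample exclusion
# ---------------------------------------------------------------------------

def exclude_flagged_samples(
    ae_frame: pd.DataFrame,
    exclusions: Iterable[tuple[str, str]] = (),
    outlier_rule: bool = False,
    outlier_margin: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop explicitly excluded and (optionally) low-AE-outlier samples.

    ``exclusions`` is a list of (donor, tissue) pairs — e.g. an
    EBV-transformed lymphoblast sample whose XCI state is untrustworthy.
    With ``outlier_rule`` on, a tissue whose median nonPAR AE falls more
    than ``outlier_margin`` below the donor's cross-tissue median of
    medians is also dropped — the operational form of excluding a tissue
    with conspicuously lower skew than the donor's other tissues.

    Returns (retained frame, exclusion log with columns donor, tissue,
    reason).
    """
    log_rows: list[tuple[str, str, str]] = []
    excl = set(exclusions)
    out = ae_frame
    if excl and not out.empty:
        mask = [(d, t) in excl for d, t in zip(out["donor"], out["tissue"])]
        mask = np.asarray(mask, dtype=bool)
        for donor, tissue in sorted({(d, t) for d, t in zip(out.loc[mask, "donor"],
                                                            out.loc[mask, "tissue"])}):
            log_rows.append((donor, tissue, "exclusion list"))
        out = out[~mask]
    if outlier_rule and not out.empty:
        nonpar = out[out["parRegion"] == "nonPAR"]
        medians = nonpar.groupby(["donor", "tissue"])["aeValue"].median()
        to_drop: set[tuple[str, str]] = set()
        for donor, tissue_medians in medians.groupby(level=0):
            center = tissue_medians.median()
            for (d, tissue), med in tissue_medians.items():
                if med < center - outlier_margin:
                    to_drop.add((d, tissue))
                    log_rows.append((d, tissue,
                                     f"median nonPAR AE {med:.3f} < donor median {center:.3f} - {outlier_margin}"))
        if to_drop:
            mask = np.asarray([(d, t) in to_drop for d, t in zip(out["donor"], out["tissue"])])
            out = out[~mask]
    for donor, tissue, reason in log_rows:
        logger.info("excluding sample %s/%s: %s", donor, tissue, reason)
    log = pd.DataFrame(log_rows, columns=["donor", "tissue", "reason"])
    return out.reset_index(drop=True), log


# ---------------------------------------------------------------------------
# One-call pipeline stage
# ---------------------------------------------------------------------------

def compute_ae_table(
    counts: pd.DataFrame,
    genotypes: pd.DataFrame,
    annotations: Sequence[GeneAnnotation],
    policy: FilterPolicy,
    with_xi: bool = False,
) -> pd.DataFrame:
    """Full allele-count -> AE-table stage for one mode.

    Applies genotype filtering, assay merging, RNA-depth filtering, gene
    mapping and SNP-per-gene selection, then computes AE (and, when
    ``with_xi``, the donor-fixed Xi columns used by the escape test).
    """
    stage = filter_counts_by_genotype(counts, genotypes, policy)
    logger.info("genotype filter: %d of %d count rows retained", len(stage), len(counts))
    stage = merge_assay_counts(stage)
    stage = apply_rna_filters(stage, policy)
    logger.info("RNA filter: %d rows retained", len(stage))
    stage = map_counts_to_genes(stage, annotations)
    stage = select_snp_per_gene(stage, policy.mode)
    ae = build_ae_frame(stage)
    logger.info("AE table: %d gene x tissue rows", len(ae))
    if with_xi:
        ae = add_xi_columns(ae)
    return ae
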