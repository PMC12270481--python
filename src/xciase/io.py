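"""Readers, writers and shared annotation types.

File dialects handled here:

* genotypes: VCF v4.x with a per-sample ``AD`` FORMAT field (read via
  :mod:`cyvcf2`; a minimal text writer is provided for simulated data),
* allele counts: tab-separated tables in the GATK ASEReadCounter column
  layout (``contig, position, refAllele, altAllele, refCount, altCount,
  totalCount``) with optional provenance columns ``donor, sample, tissue,
  assay``,
* gene annotation: a six-column TSV (``geneId, geneName, contig, start,
  end, priorStatus``) or a GTF (``gene`` features).

All coordinates are 1-based inclusive internally (VCF convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

Assay = Literal["WES", "WGS"]
ParRegion = Literal["nonPAR", "PAR1", "PAR2"]
PriorStatus = Literal["escape", "inactive", "variable", "unknown"]

#: GRCh38 pseudoautosomal regions, 1-based inclusive.  These are
#: assembly-definition defaults; override via :class:`ParIntervals` or the
#: pipeline config when working on another build.
GRCH38_PAR1 = (10_001, 2_781_479)
GRCH38_PAR2 = (155_701_383, 156_030_895)

ALLELE_COUNT_COLUMNS = [
    "contig",
    "position",
    "refAllele",
    "altAllele",
    "refCount",
    "altCount",
    "totalCount",
]
PROVENANCE_COLUMNS = ["donor", "sample", "tissue", "assay"]


class FormatError(ValueError):
    """A file does not conform to its declared dialect."""


class ValidationError(ValueError):
    """A record violates a domain invariant."""


@dataclass(frozen=True, order=True)
class SnpKey:
    """Identity of a biallelic SNP: contig, 1-based position and alleles."""

    contig: str
    position: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if not self.contig:
            raise ValidationError("SnpKey.contig must be non-empty")
        if self.position < 1:
            raise ValidationError(f"SnpKey.position must be >= 1, got {self.position}")
        if self.ref == self.alt:
            raise ValidationError(f"SnpKey ref == alt ({self.ref!r}) at {self.contig}:{self.position}")


@dataclass(frozen=True)
class HetSnpGenotype:
    """A heterozygous genotype call with per-allele sequencing depth."""

    key: SnpKey
    donor: str
    assay: Assay
    ref_depth: int
    alt_depth: int
    passed_variant_filter: bool

    def __post_init__(self) -> None:
        if self.ref_depth < 0 or self.alt_depth < 0:
            raise ValidationError("allele depths must be non-negative")
        if self.passed_variant_filter and self.ref_depth + self.alt_depth == 0:
            raise ValidationError("a PASS het genotype must have positive total depth")


@dataclass(frozen=True)
class AlleleCountRecord:
    """RNA read counts over the two alleles of one hetSNP in one sample.

    ``assay`` records which genotype source (WES or WGS pipeline) supplied
    the site; ``total_count`` may exceed ``ref_count + alt_count`` because
    ASEReadCounter also tallies other bases.
    """

    key: SnpKey
    donor: str
    sample: str
    tissue: str
    ref_count: int
    alt_count: int
    total_count: int
    assay: Assay = "WES"

    def __post_init__(self) -> None:
        if min(self.ref_count, self.alt_count, self.total_count) < 0:
            raise ValidationError("read counts must be non-negative")
        if self.total_count < self.ref_count + self.alt_count:
            raise ValidationError(
                f"totalCount {self.total_count} < refCount+altCount "
                f"{self.ref_count + self.alt_count} at {self.key.contig}:{self.key.position}"
            )


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene interval with PAR membership and optional prior XCI status."""

    gene_id: str
    gene_name: str
    contig: str
    start: int
    end: int
    par_region: ParRegion = "nonPAR"
    prior_status: PriorStatus = "unknown"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(f"gene {self.gene_id}: start {self.start} > end {self.end}")


@dataclass(frozen=True)
class ParIntervals:
    """PAR1/PAR2 intervals on the X contig, 1-based inclusive."""

    contig: str = "chrX"
    par1: tuple[int, int] = GRCH38_PAR1
    par2: tuple[int, int] = GRCH38_PAR2


def annotate_par(gene: GeneAnnotation, par_intervals: ParIntervals | None = None) -> GeneAnnotation:
    """Set ``par_region`` from interval overlap with the configured PARs.

    A gene straddling a PAR boundary is classified by its body midpoint, so
    every gene carries exactly one label.  Genes off the X contig are
    ``nonPAR`` (with a warning: they should not normally be here).
    """
    par = par_intervals or ParIntervals()
    if gene.contig != par.contig:
        logger.warning("gene %s on %s is not on the X contig %s; parRegion=nonPAR",
                       gene.gene_id, gene.contig, par.contig)
        return replace(gene, par_region="nonPAR")
    mid = (gene.start + gene.end) // 2
    if par.par1[0] <= mid <= par.par1[1]:
        region: ParRegion = "PAR1"
    elif par.par2[0] <= mid <= par.par2[1]:
        region = "PAR2"
    else:
        region = "nonPAR"
    return replace(gene, par_region=region)


# ---------------------------------------------------------------------------
# VCF genotypes
# ---------------------------------------------------------------------------

def read_het_snps(
    vcf_path: str | Path,
    donor: str,
    assay: Assay,
    contig: str = "chrX",
) -> list[HetSnpGenotype]:
    """Extract biallelic heterozygous genotypes for one donor on one contig.

    ``passed_variant_filter`` mirrors the VCF FILTER column (PASS or missing
    => True).  Multi-allelic sites are skipped with a warning; homozygous
    and off-contig sites are silently ignored.
    """
    frame = read_het_snp_table(vcf_path, assay=assay, contig=contig)
    if donor not in set(frame["donor"]) and donor not in _vcf_samples(vcf_path):
        raise KeyError(f"donor {donor!r} not among samples of {vcf_path}")
    return het_snp_frame_to_records(frame[frame["donor"] == donor])


def _vcf_samples(vcf_path: str | Path) -> list[str]:
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    try:
        return list(vcf.samples)
    finally:
        vcf.close()


def read_het_snp_table(
    vcf_path: str | Path,
    assay: Assay,
    contig: str = "chrX",
) -> pd.DataFrame:
    """All-donor variant of :func:`read_het_snps`, as a DataFrame.

    Columns: donor, contig, position, ref, alt, assay, refDepth, altDepth,
    passedVariantFilter.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(vcf_path))
    except Exception as exc:  # cyvcf2 raises bare OSError on malformed input
        raise FormatError(f"cannot open VCF {vcf_path}: {exc}") from exc
    rows: list[tuple] = []
    try:
        samples = list(vcf.samples)
        for variant in vcf:
            if variant.CHROM != contig:
                continue
            if len(variant.ALT) != 1:
                logger.warning("skipping multi-allelic site %s:%d", variant.CHROM, variant.POS)
                continue
            ad = variant.format("AD")
            if ad is None:
                raise FormatError(f"VCF {vcf_path} lacks the AD FORMAT field at "
                                  f"{variant.CHROM}:{variant.POS}")
            passed = variant.FILTER is None or variant.FILTER == "PASS"
            gt_types = variant.gt_types  # 1 == heterozygous
            for i, sample in enumerate(samples):
                if gt_types[i] != 1:
                    continue
                ref_depth, alt_depth = int(ad[i][0]), int(ad[i][1])
                rows.append((sample, variant.CHROM, variant.POS, variant.REF,
                             variant.ALT[0], assay, ref_depth, alt_depth, passed))
    finally:
        vcf.close()
    return pd.DataFrame(
        rows,
        columns=["donor", "contig", "position", "ref", "alt", "assay",
                 "refDepth", "altDepth", "passedVariantFilter"],
    )


def het_snp_frame_to_records(frame: pd.DataFrame) -> list[HetSnpGenotype]:
    return [
        HetSnpGenotype(
            key=SnpKey(row.contig, int(row.position), row.ref, row.alt),
            donor=row.donor,
            assay=row.assay,
            ref_depth=int(row.refDepth),
            alt_depth=int(row.altDepth),
            passed_variant_filter=bool(row.passedVariantFilter),
        )
        for row in frame.itertuples(index=False)
    ]


def write_genotype_vcf(genotypes: pd.DataFrame, path: str | Path, contig: str = "chrX") -> None:
    """Write a genotype table as a minimal VCF v4.2 with GT:AD per sample.

    Expects the :func:`read_het_snp_table` column layout plus, optionally,
    rows for homozygous samples (gt column with '0/0', '1/1'; absent rows
    are emitted as missing './.').
    """
    donors = sorted(genotypes["donor"].unique())
    sites = (
        genotypes[["contig", "position", "ref", "alt"]]
        .drop_duplicates()
        .sort_values(["contig", "position"])
    )
    by_site: dict[tuple, dict[str, tuple[int, int, bool]]] = {}
    for row in genotypes.itertuples(index=False):
        by_site.setdefault((row.contig, int(row.position), row.ref, row.alt), {})[row.donor] = (
            int(row.refDepth), int(row.altDepth), bool(row.passedVariantFilter)
        )
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={contig}>\n")
        fh.write('##FILTER=<ID=PASS,Description="All filters passed">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(donors) + "\n")
        for site in sites.itertuples(index=False):
            key = (site.contig, int(site.position), site.ref, site.alt)
            calls = by_site[key]
            passed = all(c[2] for c in calls.values())
            cols = [site.contig, str(site.position), ".", site.ref, site.alt, ".",
                    "PASS" if passed else "lowqual", ".", "GT:AD"]
            for donor in donors:
                if donor in calls:
                    rd, ad, _ = calls[donor]
                    cols.append(f"0/1:{rd},{ad}")
                else:
                    cols.append("./.:.,.")
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# Allele-count tables
# ---------------------------------------------------------------------------

def read_allele_count_table(
    path: str | Path,
    donor: str | None = None,
    sample: str | None = None,
    tissue: str | None = None,
    assay: Assay | None = None,
) -> pd.DataFrame:
    """Read an ASEReadCounter-style TSV into a validated DataFrame.

    Provenance (donor/sample/tissue/assay) may come from columns in the
    file or from the keyword arguments; arguments override columns.
    """
    try:
        frame = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise FormatError(f"cannot parse allele-count table {path}: {exc}") from exc
    missing = [c for c in ALLELE_COUNT_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"allele-count table {path} missing required column(s): {', '.join(missing)}")
    overrides = {"donor": donor, "sample": sample, "tissue": tissue, "assay": assay}
    for col, value in overrides.items():
        if value is not None:
            frame[col] = value
        elif col not in frame.columns:
            frame[col] = "NA" if col != "assay" else "WES"
    frame = frame[PROVENANCE_COLUMNS + ALLELE_COUNT_COLUMNS].copy()
    for col in ("position", "refCount", "altCount", "totalCount"):
        frame[col] = frame[col].astype(int)
    _validate_allele_counts(frame, path)
    return frame.reset_index(drop=True)


def _validate_allele_counts(frame: pd.DataFrame, path: str | Path | None = None) -> None:
    where = f" in {path}" if path else ""
    counts = frame[["refCount", "altCount", "totalCount"]].to_numpy()
    if (counts < 0).any():
        raise ValidationError(f"negative read count{where}")
    bad = counts[:, 2] < counts[:, 0] + counts[:, 1]
    if bad.any():
        i = int(bad.argmax())
        row = frame.iloc[i]
        raise ValidationError(
            f"totalCount < refCount+altCount at {row['contig']}:{row['position']}{where}"
        )
    if (frame["position"] < 1).any():
        raise ValidationError(f"non-positive position{where}")


def read_allele_counts(
    path: str | Path,
    donor: str | None = None,
    sample: str | None = None,
    tissue: str | None = None,
    assay: Assay | None = None,
) -> list[AlleleCountRecord]:
    """Record-level twin of :func:`read_allele_count_table`."""
    return allele_count_frame_to_records(
        read_allele_count_table(path, donor=donor, sample=sample, tissue=tissue, assay=assay)
    )


def allele_count_frame_to_records(frame: pd.DataFrame) -> list[AlleleCountRecord]:
    return [
        AlleleCountRecord(
            key=SnpKey(row.contig, int(row.position), row.refAllele, row.altAllele),
            donor=row.donor,
            sample=row.sample,
            tissue=row.tissue,
            ref_count=int(row.refCount),
            alt_count=int(row.altCount),
            total_count=int(row.totalCount),
            assay=row.assay,
        )
        for row in frame.itertuples(index=False)
    ]


def allele_count_records_to_frame(records: Iterable[AlleleCountRecord]) -> pd.DataFrame:
    rows = [
        (r.donor, r.sample, r.tissue, r.assay, r.key.contig, r.key.position,
         r.key.ref, r.key.alt, r.ref_count, r.alt_count, r.total_count)
        for r in records
    ]
    return pd.DataFrame(rows, columns=PROVENANCE_COLUMNS + ALLELE_COUNT_COLUMNS)


def write_allele_count_table(frame: pd.DataFrame, path: str | Path) -> None:
    """Write an allele-count DataFrame as TSV (exact integer round-trip)."""
    frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Gene annotation
# ---------------------------------------------------------------------------

def read_gene_annotations(
    path: str | Path,
    par_intervals: ParIntervals | None = None,
) -> list[GeneAnnotation]:
    """Read gene annotation from a 6-column TSV or a GTF and assign PARs.

    The TSV layout is ``geneId  geneName  contig  start  end  priorStatus``
    (1-based inclusive coordinates).  Files ending in ``.gtf`` are parsed as
    GTF ``gene`` features with ``gene_id``/``gene_name`` attributes.
    """
    path = Path(path)
    if path.suffix.lower() == ".gtf":
        genes = _read_genes_gtf(path)
    else:
        frame = pd.read_csv(path, sep="\t")
        required = ["geneId", "geneName", "contig", "start", "end"]
        missing = [c for c in required if c not in frame.columns]
        if missing:
            raise FormatError(f"gene table {path} missing column(s): {', '.join(missing)}")
        if "priorStatus" not in frame.columns:
            frame["priorStatus"] = "unknown"
        frame["priorStatus"] = frame["priorStatus"].fillna("unknown")
        genes = [
            GeneAnnotation(
                gene_id=row.geneId, gene_name=row.geneName, contig=row.contig,
                start=int(row.start), end=int(row.end), prior_status=row.priorStatus,
            )
            for row in frame.itertuples(index=False)
        ]
    return [annotate_par(g, par_intervals) for g in genes]


def _read_genes_gtf(path: Path) -> list[GeneAnnotation]:
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", force=True, keep_order=True,
                            merge_strategy="warning", disable_infer_genes=True,
                            disable_infer_transcripts=True)
    genes = []
    for feat in db.features_of_type("gene"):
        gene_id = feat.attributes.get("gene_id", [feat.id])[0]
        gene_name = feat.attributes.get("gene_name", [gene_id])[0]
        genes.append(GeneAnnotation(gene_id=gene_id, gene_name=gene_name,
                                    contig=feat.seqid, start=feat.start, end=feat.end))
    return genes


def write_gene_annotations(genes: Sequence[GeneAnnotation], path: str | Path) -> None:
    frame = pd.DataFrame(
        [(g.gene_id, g.gene_name, g.contig, g.start, g.end, g.prior_status) for g in genes],
        columns=["geneId", "geneName", "contig", "start", "end", "priorStatus"],
    )
    frame.to_csv(path, sep="\t", index=False)


def bed_to_inclusive(start0: int, end0: int) -> tuple[int, int]:
    """Convert a half-open 0-based (BED) interval to 1-based inclusive."""
    return start0 + 1, end0
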