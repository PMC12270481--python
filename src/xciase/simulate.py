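"""Synthetic donors, genotypes and allele-count tables.

The generative model mirrors what the analysis assumes about bulk RNA-seq
of female tissues.  Every donor carries an XCI skew ``delta`` in [0.5, 1]:
the fraction of cells inactivating the same parental X.  ``delta = 0.5`` is
perfectly balanced mosaicism, ``delta = 1.0`` is non-mosaic XCI (nmXCI).
Every X-linked gene carries an inactive-X expression fraction ``pi`` in
[0, 0.5]: the expected share of the gene's RNA reads contributed by the Xi
haplotype in a fully skewed tissue.  Inactive genes leak a little
(``pi = 0.005`` by default), constitutive escape genes sit at
``pi ~ U(0.15, 0.40)``, PAR genes are fully biallelic (``pi = 0.5``), and
variable genes escape in a per-tissue Bernoulli fashion.

For a hetSNP in a donor with skew ``delta`` and gene fraction ``pi``, the
expected fraction of reads from the haplotype that is Xi in the majority
cell lineage is

    f = delta * pi + (1 - delta) * (1 - pi)

so a balanced mosaic donor (``delta = 0.5``) yields ``f = 0.5`` for every
gene — which is exactly why mosaic tissues carry no allelic signal and the
analysis needs nmXCI females.  Read counts are drawn (beta-)binomially at a
negative-binomial sequencing depth, optionally pushed through a reference
mapping bias, and the haplotype-to-ref/alt assignment is randomised per
donor-SNP.

Truth labels are emitted alongside the data and are never consumed by the
pipeline; the writer keeps them in a separate ``truth/`` directory.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .io import (
    ALLELE_COUNT_COLUMNS,
    PROVENANCE_COLUMNS,
    GeneAnnotation,
    ParIntervals,
    annotate_par,
    write_allele_count_table,
    write_gene_annotations,
    write_genotype_vcf,
)

GeneClass = Literal["PAR", "escape", "inactive", "variable"]

#: Tissue codes in the GTEx-style abbreviation convention.
TISSUE_CODES = (
    "muscle", "skin-leg", "thyroid", "adipose-subc", "artery-tibi",
    "esophagus-muco", "nerve", "adipose-visc", "ovary", "uterus",
    "pituitary", "lung", "heart", "liver", "brain-cortex", "spleen",
    "pancreas", "stomach", "colon-trans", "whole-blood",
)

#: Screen-tissue sampling weights, shaped like the single-tissue screen mix
#: (muscle dominates, skin-leg next, a scattering of others).
_SCREEN_TISSUE_WEIGHTS = {
    "muscle": 239, "skin-leg": 21, "thyroid": 1, "adipose-subc": 2,
    "artery-tibi": 2, "esophagus-muco": 2, "nerve": 2, "adipose-visc": 1,
    "ovary": 1, "uterus": 1,
}

_NONPAR_SPAN = (3_000_000, 155_000_000)


class SimConfigError(ValueError):
    """A simulation parameter is outside its valid domain."""


@dataclass(frozen=True)
class GeneSpec:
    """Ground-truth description of one simulated gene."""

    gene_id: str
    gene_class: GeneClass
    xi_fraction: float
    contig: str = "chrX"
    start: int = 0
    end: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.xi_fraction <= 0.5:
            raise SimConfigError(
                f"gene {self.gene_id}: xi_fraction must lie in [0, 0.5], got {self.xi_fraction}"
            )


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort.

    Defaults reproduce the screening study design: 285 female donors, three
    of them fully skewed (nmXCI), the rest mosaic with skew uniform on
    [0.5, 0.9]; a 400-gene X chromosome with 5% PAR, 15% constitutive
    escape, 10% variable and 70% inactive genes; negative-binomial RNA
    depth with mean 50.
    """

    n_donors: int = 285
    n_nmxci: int = 3
    nmxci_delta: float = 1.0
    mosaic_skew_range: tuple[float, float] = (0.5, 0.9)
    skews: Sequence[float] | None = None  # explicit per-donor deltas override

    tissues: Sequence[str] | int = 1  # int n => first n of TISSUE_CODES
    screen_tissue_mix: bool = True  # single-tissue cohorts sample the screen mix

    genes: Sequence[GeneSpec] | None = None
    n_genes: int = 400
    class_fractions: dict[str, float] = field(
        default_factory=lambda: {"PAR": 0.05, "escape": 0.15, "variable": 0.10, "inactive": 0.70}
    )
    escape_pi_range: tuple[float, float] = (0.15, 0.40)
    inactive_leak_pi: float = 0.005
    variable_escape_prob: float = 0.5
    snps_per_gene: int = 2
    het_prob: float = 0.75

    rna_depth_mean: float = 50.0
    rna_depth_dispersion: float = 5.0
    assays: Sequence[str] = ("WES", "WGS")
    wes_depth_mean: float = 60.0
    wgs_depth_mean: float = 35.0
    genotype_depth_dispersion: float = 10.0

    reference_bias: float = 0.5
    overdispersion: float | None = None  # beta-binomial concentration; None = binomial

    seed: int = 0
    truth_seed: int | None = None  # defaults to `seed`; set to freeze truth across noise draws

    def __post_init__(self) -> None:
        if self.n_donors < 0 or self.n_nmxci < 0:
            raise SimConfigError("donor counts must be non-negative")
        if self.n_nmxci > self.n_donors:
            raise SimConfigError("n_nmxci cannot exceed n_donors")
        lo, hi = self.mosaic_skew_range
        for delta in (self.nmxci_delta, lo, hi, *(self.skews or ())):
            if not 0.5 <= delta <= 1.0:
                raise SimConfigError(f"skew delta must lie in [0.5, 1.0], got {delta}")
        if self.skews is not None and len(self.skews) != self.n_donors:
            raise SimConfigError("skews must have one entry per donor")
        if not 0.0 < self.reference_bias < 1.0:
            raise SimConfigError("reference_bias must lie in (0, 1)")
        if self.overdispersion is not None and self.overdispersion <= 0:
            raise SimConfigError("overdispersion concentration must be positive")
        if not 0.0 <= self.inactive_leak_pi <= 0.5:
            raise SimConfigError("inactive_leak_pi must lie in [0, 0.5]")
        if not (0.0 <= self.escape_pi_range[0] <= self.escape_pi_range[1] <= 0.5):
            raise SimConfigError("escape_pi_range must be within [0, 0.5]")
        if self.snps_per_gene < 1:
            raise SimConfigError("snps_per_gene must be >= 1")

    def tissue_list(self) -> list[str]:
        if isinstance(self.tissues, int):
            return list(TISSUE_CODES[: self.tissues])
        return list(self.tissues)

    @classmethod
    def screen_defaults(cls, seed: int = 0, **overrides) -> "SimConfig":
        """The 285-donor single-tissue screening design."""
        return cls(seed=seed, **overrides)

    @classmethod
    def detailed_defaults(cls, seed: int = 0, **overrides) -> "SimConfig":
        """A small all-nmXCI cohort with multi-tissue coverage."""
        defaults = dict(n_donors=3, n_nmxci=3, tissues=10, screen_tissue_mix=False)
        defaults.update(overrides)
        return cls(seed=seed, **defaults)


@dataclass
class SimTruth:
    """Ground truth emitted next to the data; never read by the pipeline."""

    donors: pd.DataFrame  # donor, delta, is_nmxci
    genes: pd.DataFrame  # geneId, geneClass, xiFraction, contig, start, end
    gene_tissue: pd.DataFrame  # geneId, tissue, escaping, xiFraction (variable genes)
    donor_haplotypes: pd.DataFrame  # donor, contig, position, xiAlleleTrue

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.donors.to_csv(outdir / "truth_donors.tsv", sep="\t", index=False)
        self.genes.to_csv(outdir / "truth_genes.tsv", sep="\t", index=False)
        self.gene_tissue.to_csv(outdir / "truth_gene_tissue.tsv", sep="\t", index=False)
        self.donor_haplotypes.to_csv(outdir / "truth_donor_haplotypes.tsv", sep="\t", index=False)


@dataclass
class SimData:
    """One simulated cohort: inputs for the pipeline plus separate truth."""

    genotypes: pd.DataFrame  # read_het_snp_table layout, all assays stacked
    counts: pd.DataFrame  # allele-count layout with provenance columns
    annotations: list[GeneAnnotation]
    truth: SimTruth

    def write(self, outdir: str | Path, par_intervals: ParIntervals | None = None) -> dict[str, Path]:
        """Write pipeline inputs to ``outdir`` and truth to ``outdir/truth``."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        for assay in sorted(self.genotypes["assay"].unique()):
            path = outdir / f"genotypes_{assay.lower()}.vcf"
            write_genotype_vcf(self.genotypes[self.genotypes["assay"] == assay], path)
            paths[f"genotypes_{assay.lower()}"] = path
        paths["counts"] = outdir / "allele_counts.tsv"
        write_allele_count_table(self.counts, paths["counts"])
        paths["genes"] = outdir / "genes.tsv"
        write_gene_annotations(self.annotations, paths["genes"])
        self.truth.write(outdir / "truth")
        paths["truth"] = outdir / "truth"
        return paths


def default_gene_panel(config: SimConfig, rng: np.random.Generator) -> list[GeneSpec]:
    """Lay out a gene panel along chrX matching the configured class mix.

    PAR genes are placed inside the GRCh38 PAR1/PAR2 intervals; all other
    genes are spaced across the nonPAR body of the chromosome.  Class
    labels are interleaved deterministically from the class fractions, then
    shuffled positionally with the truth RNG.
    """
    n = config.n_genes
    fractions = config.class_fractions
    counts = {c: int(round(f * n)) for c, f in fractions.items()}
    counts["inactive"] = n - sum(v for c, v in counts.items() if c != "inactive")
    classes: list[str] = []
    for cls in ("PAR", "escape", "variable", "inactive"):
        classes.extend([cls] * counts.get(cls, 0))
    order = rng.permutation(n)
    classes = [classes[i] for i in order]

    n_par = counts.get("PAR", 0)
    par = ParIntervals()
    par_starts = np.linspace(par.par1[0] + 1000, par.par1[1] - 30_000,
                             max(n_par, 1)).astype(int)
    nonpar_starts = np.linspace(_NONPAR_SPAN[0], _NONPAR_SPAN[1],
                                max(n - n_par, 1)).astype(int)
    gene_len = 20_000

    genes: list[GeneSpec] = []
    i_par = i_non = 0
    for i, cls in enumerate(classes):
        if cls == "PAR":
            start = int(par_starts[i_par]); i_par += 1
        else:
            start = int(nonpar_starts[i_non]); i_non += 1
        if cls == "PAR":
            pi = 0.5
        elif cls == "inactive":
            pi = config.inactive_leak_pi
        else:  # escape or variable: baseline escape magnitude
            pi = float(rng.uniform(*config.escape_pi_range))
        genes.append(GeneSpec(gene_id=f"G{i + 1:04d}", gene_class=cls, xi_fraction=pi,
                              start=start, end=start + gene_len))
    return genes


def _negative_binomial(rng: np.random.Generator, mean: float, dispersion: float,
                       size) -> np.ndarray:
    # NB with mean m and size r: p = r / (r + m)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size)


def _biased(p: np.ndarray, bias: float) -> np.ndarray:
    """Push a reference-read probability through a mapping bias.

    ``bias`` is the probability that a read drawn equally from either allele
    is counted as reference; 0.5 is unbiased.  Applied on the odds scale so
    degenerate probabilities (0 and 1) are preserved.
    """
    if bias == 0.5:
        return p
    return bias * p / (bias * p + (1.0 - bias) * (1.0 - p))


def simulate_dataset(config: SimConfig) -> SimData:
    """Generate genotypes, allele-count tables and truth for one cohort."""
    rng_truth = np.random.default_rng(
        np.random.SeedSequence([config.truth_seed if config.truth_seed is not None else config.seed, 1])
    )
    rng_noise = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))

    genes = list(config.genes) if config.genes is not None else default_gene_panel(config, rng_truth)
    n_genes = len(genes)
    tissues = config.tissue_list()
    n_tissues = len(tissues)

    donors = [f"D{i + 1:04d}" for i in range(config.n_donors)]
    if config.skews is not None:
        deltas = np.asarray(config.skews, dtype=float)
        is_nmxci = deltas >= 0.995
    else:
        deltas = rng_truth.uniform(*config.mosaic_skew_range, size=config.n_donors)
        nmxci_idx = rng_truth.choice(config.n_donors, size=config.n_nmxci, replace=False) \
            if config.n_donors else np.array([], dtype=int)
        deltas[nmxci_idx] = config.nmxci_delta
        is_nmxci = deltas >= 0.995

    # single-tissue cohorts draw each donor's tissue from the screen mix
    if n_tissues == 1 and config.screen_tissue_mix and config.n_donors:
        mix = list(_SCREEN_TISSUE_WEIGHTS.items())
        probs = np.array([w for _, w in mix], dtype=float)
        probs /= probs.sum()
        donor_tissue = rng_truth.choice([t for t, _ in mix], size=config.n_donors, p=probs)
    else:
        donor_tissue = None

    # SNP positions and alleles
    bases = np.array(list("ACGT"))
    site_gene_idx = np.repeat(np.arange(n_genes), config.snps_per_gene)
    positions = np.empty(n_genes * config.snps_per_gene, dtype=int)
    for g, spec in enumerate(genes):
        span = max(spec.end - spec.start, config.snps_per_gene + 1)
        offs = rng_truth.choice(span, size=config.snps_per_gene, replace=False)
        positions[g * config.snps_per_gene:(g + 1) * config.snps_per_gene] = spec.start + np.sort(offs)
    n_sites = positions.size
    ref_idx = rng_truth.integers(0, 4, size=n_sites)
    alt_idx = (ref_idx + rng_truth.integers(1, 4, size=n_sites)) % 4
    refs, alts = bases[ref_idx], bases[alt_idx]

    # per-tissue Xi fraction matrix (n_tissues, n_sites)
    gene_pi = np.array([g.xi_fraction for g in genes])
    gene_class = np.array([g.gene_class for g in genes])
    pi_tissue_gene = np.tile(gene_pi, (n_tissues, 1))
    var_mask = gene_class == "variable"
    escaping = np.zeros((n_tissues, n_genes), dtype=bool)
    if var_mask.any():
        escaping[:, var_mask] = rng_truth.random((n_tissues, int(var_mask.sum()))) < config.variable_escape_prob
        var_pi = rng_truth.uniform(*config.escape_pi_range, size=(n_tissues, int(var_mask.sum())))
        block = np.where(escaping[:, var_mask], var_pi, config.inactive_leak_pi)
        pi_tissue_gene[:, var_mask] = block
    pi_site = pi_tissue_gene[:, site_gene_idx]  # (n_tissues, n_sites)

    # genotype structure
    het = rng_truth.random((config.n_donors, n_sites)) < config.het_prob
    hap_is_ref = rng_truth.random((config.n_donors, n_sites)) < 0.5

    # RNA counts, one tissue layer at a time
    count_frames: list[pd.DataFrame] = []
    delta_col = deltas[:, None]  # (n_donors, 1)
    for t, tissue in enumerate(tissues):
        f = delta_col * pi_site[t][None, :] + (1.0 - delta_col) * (1.0 - pi_site[t][None, :])
        depth = _negative_binomial(rng_noise, config.rna_depth_mean,
                                   config.rna_depth_dispersion, (config.n_donors, n_sites))
        p_ref = np.where(hap_is_ref, f, 1.0 - f)
        p_ref = _biased(p_ref, config.reference_bias)
        if config.overdispersion is not None:
            c = config.overdispersion
            a = np.clip(p_ref * c, 1e-9, None)
            b = np.clip((1.0 - p_ref) * c, 1e-9, None)
            p_ref = rng_noise.beta(a, b)
        ref_counts = rng_noise.binomial(depth, p_ref)
        keep = het & (depth > 0)
        d_idx, s_idx = np.nonzero(keep)
        if d_idx.size == 0:
            continue
        tissue_labels = donor_tissue[d_idx] if donor_tissue is not None else np.full(d_idx.size, tissue)
        frame = pd.DataFrame({
            "donor": np.array(donors, dtype=object)[d_idx],
            "tissue": tissue_labels,
            "contig": np.array([genes[0].contig if genes else "chrX"], dtype=object).repeat(d_idx.size),
            "position": positions[s_idx],
            "refAllele": refs[s_idx],
            "altAllele": alts[s_idx],
            "refCount": ref_counts[keep],
            "altCount": depth[keep] - ref_counts[keep],
        })
        frame["totalCount"] = frame["refCount"] + frame["altCount"]
        count_frames.append(frame)

    counts = (pd.concat(count_frames, ignore_index=True) if count_frames
              else pd.DataFrame(columns=["donor", "tissue", "contig", "position", "refAllele",
                                         "altAllele", "refCount", "altCount", "totalCount"]))
    counts["sample"] = counts["donor"].astype(str) + ":" + counts["tissue"].astype(str)

    # genotype depths per assay; RNA counts are replicated per genotype source,
    # as joining the per-assay ASEReadCounter outputs does upstream
    geno_frames: list[pd.DataFrame] = []
    d_idx, s_idx = np.nonzero(het)
    for assay in config.assays:
        mean = config.wes_depth_mean if assay == "WES" else config.wgs_depth_mean
        depth = _negative_binomial(rng_noise, mean, config.genotype_depth_dispersion, d_idx.size)
        depth = np.maximum(depth, 1)
        ref_depth = rng_noise.binomial(depth, 0.5)
        geno_frames.append(pd.DataFrame({
            "donor": np.array(donors, dtype=object)[d_idx],
            "contig": "chrX",
            "position": positions[s_idx],
            "ref": refs[s_idx],
            "alt": alts[s_idx],
            "assay": assay,
            "refDepth": ref_depth,
            "altDepth": depth - ref_depth,
            "passedVariantFilter": True,
        }))
    genotypes = (pd.concat(geno_frames, ignore_index=True) if geno_frames
                 else pd.DataFrame(columns=["donor", "contig", "position", "ref", "alt",
                                            "assay", "refDepth", "altDepth", "passedVariantFilter"]))

    assay_frames = []
    for assay in config.assays:
        with_assay = counts.copy()
        with_assay["assay"] = assay
        assay_frames.append(with_assay)
    counts = (pd.concat(assay_frames, ignore_index=True) if assay_frames else counts)
    counts = counts[PROVENANCE_COLUMNS + ALLELE_COUNT_COLUMNS].sort_values(
        ["donor", "tissue", "assay", "position"], kind="stable").reset_index(drop=True)

    prior_map = {"PAR": "unknown", "escape": "escape", "inactive": "inactive", "variable": "variable"}
    annotations = [
        annotate_par(GeneAnnotation(
            gene_id=g.gene_id, gene_name=g.gene_id, contig=g.contig,
            start=g.start, end=g.end, prior_status=prior_map[g.gene_class],
        ))
        for g in genes
    ]

    gene_tissue_rows = []
    for t, tissue in enumerate(tissues):
        for gi in np.nonzero(var_mask)[0]:
            gene_tissue_rows.append((genes[gi].gene_id, tissue,
                                     bool(escaping[t, gi]), float(pi_tissue_gene[t, gi])))
    # the haplotype that is Xi in the majority lineage, per het donor-SNP
    hd_idx, hs_idx = np.nonzero(het)
    donor_haplotypes = pd.DataFrame({
        "donor": np.array(donors, dtype=object)[hd_idx],
        "contig": "chrX",
        "position": positions[hs_idx],
        "xiAlleleTrue": np.where(hap_is_ref[het], "ref", "alt"),
    })
    truth = SimTruth(
        donors=pd.DataFrame({"donor": donors, "delta": deltas, "is_nmxci": is_nmxci}),
        genes=pd.DataFrame({
            "geneId": [g.gene_id for g in genes],
            "geneClass": gene_class,
            "xiFraction": gene_pi,
            "contig": [g.contig for g in genes],
            "start": [g.start for g in genes],
            "end": [g.end for g in genes],
        }),
        gene_tissue=pd.DataFrame(gene_tissue_rows,
                                 columns=["geneId", "tissue", "escaping", "xiFraction"]),
        donor_haplotypes=donor_haplotypes,
    )
    return SimData(genotypes=genotypes, counts=counts, annotations=annotations, truth=truth)


def simulate_screen_cohort(config: SimConfig | None = None, seed: int = 0) -> SimData:
    """One-tissue-per-donor cohort matching the nmXCI screening design.

    Genotypes come from the WES pipeline only, as in the released
    exome-based screen.  Donors with true ``delta >= 0.995`` carry the
    nmXCI truth label.
    """
    if config is None:
        config = SimConfig.screen_defaults(seed=seed)
    from dataclasses import replace as dc_replace

    cfg = dc_replace(config, tissues=1, assays=("WES",))
    return simulate_dataset(cfg)
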