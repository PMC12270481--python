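"""Allelic-expression computation, filtering, merging and Xi assignment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from xciase import ase
from xciase.ase import (
    FilterPolicy,
    add_xi_columns,
    apply_genotype_filters,
    apply_rna_filters,
    assign_xi_allele,
    build_ae_frame,
    compute_ae,
    compute_ae_table,
    exclude_flagged_samples,
    map_counts_to_genes,
    merge_assay_counts,
    select_snp_per_gene,
)
from xciase.io import HetSnpGenotype, SnpKey, ValidationError
from xciase.simulate import GeneSpec, SimConfig, simulate_dataset


def _counts(rows, **common):
    defaults = dict(donor="d1", sample="s1", tissue="muscle", assay="WES",
                    contig="chrX", refAllele="A", altAllele="G")
    defaults.update(common)
    frame = pd.DataFrame(rows)
    for col, value in defaults.items():
        if col not in frame.columns:
            frame[col] = value
    if "totalCount" not in frame.columns:
        frame["totalCount"] = frame["refCount"] + frame["altCount"]
    return frame


class TestComputeAe:
    def test_balanced_biallelic_is_zero(self):
        assert compute_ae(50, 50) == 0.0

    def test_monoallelic_is_half(self):
        assert compute_ae(100, 0) == 0.5

    def test_2p5_percent_minor_allele(self):
        """2.5% of reads from the inactive allele sits exactly at 0.475."""
        assert compute_ae(975, 25) == pytest.approx(0.475, abs=1e-12)

    def test_zero_total_undefined(self):
        with pytest.raises(ValidationError):
            compute_ae(0, 0)

    @settings(max_examples=300, deadline=None)
    @given(st.integers(0, 10_000), st.integers(0, 10_000))
    def test_symmetry_and_range(self, a, b):
        if a + b == 0:
            return
        value = compute_ae(a, b)
        assert value == compute_ae(b, a)
        assert 0.0 <= value <= 0.5
        assert (value == 0.5) == (a == 0 or b == 0)


def _genotype(ref_depth, alt_depth, assay="WES", pos=1000):
    return HetSnpGenotype(SnpKey("chrX", pos, "A", "G"), "d1", assay,
                          ref_depth, alt_depth, True)


class TestGenotypeFilters:
    def test_screen_keeps_balanced_deep_site(self):
        kept = apply_genotype_filters([_genotype(25, 22)], FilterPolicy.screen())
        assert len(kept) == 1

    def test_screen_drops_shallow_minor_allele(self):
        kept = apply_genotype_filters([_genotype(100, 5)], FilterPolicy.screen())
        assert kept == set()

    def test_detailed_boundary_inclusive(self):
        kept = apply_genotype_filters([_genotype(10, 10)], FilterPolicy.detailed())
        assert len(kept) == 1

    def test_screen_ignores_wgs_genotypes(self):
        kept = apply_genotype_filters([_genotype(50, 50, assay="WGS")], FilterPolicy.screen())
        assert kept == set()
        kept = apply_genotype_filters([_genotype(50, 50, assay="WGS")], FilterPolicy.detailed())
        assert len(kept) == 1

    def test_minor_fraction_is_strict(self):
        # minor exactly 10% of total: 20/200 -> dropped under ">10%"
        kept = apply_genotype_filters([_genotype(180, 20)], FilterPolicy.screen())
        assert kept == set()

    def test_filter_is_monotone_in_thresholds(self):
        genotypes = [_genotype(12, 25, pos=1000), _genotype(25, 22, pos=2000),
                     _genotype(100, 11, pos=3000)]
        strict = apply_genotype_filters(genotypes, FilterPolicy.screen())
        loose = apply_genotype_filters(
            genotypes, FilterPolicy.screen(min_genotype_depth_per_allele=10))
        assert strict <= loose


class TestMergeAssayCounts:
    def test_highest_total_wins(self):
        frame = _counts([
            {"position": 1000, "refCount": 30, "altCount": 10, "assay": "WES"},
            {"position": 1000, "refCount": 60, "altCount": 30, "assay": "WGS"},
        ])
        merged = merge_assay_counts(frame)
        assert len(merged) == 1
        assert merged["assay"].iloc[0] == "WGS"
        assert merged["totalCount"].iloc[0] == 90

    def test_singleton_passes_through(self):
        frame = _counts([{"position": 1000, "refCount": 30, "altCount": 10}])
        merged = merge_assay_counts(frame)
        pd.testing.assert_frame_equal(merged, frame[merged.columns])

    def test_tie_prefers_wgs(self):
        frame = _counts([
            {"position": 1000, "refCount": 25, "altCount": 25, "assay": "WES"},
            {"position": 1000, "refCount": 30, "altCount": 20, "assay": "WGS"},
        ])
        assert merge_assay_counts(frame)["assay"].iloc[0] == "WGS"

    def test_conflicting_alleles_rejected(self):
        frame = _counts([
            {"position": 1000, "refCount": 30, "altCount": 10, "altAllele": "G"},
            {"position": 1000, "refCount": 30, "altCount": 10, "altAllele": "T",
             "assay": "WGS"},
        ])
        with pytest.raises(ValidationError):
            merge_assay_counts(frame)


class TestRnaFilters:
    @pytest.mark.parametrize("mode,total,kept", [
        ("detailed", 8, True),   # "more than seven reads"
        ("detailed", 7, False),
        ("screen", 11, True),    # ">10 reads"
        ("screen", 10, False),
    ])
    def test_strict_depth_boundaries(self, mode, total, kept):
        policy = FilterPolicy.screen() if mode == "screen" else FilterPolicy.detailed()
        frame = _counts([{"position": 1000, "refCount": total - 2, "altCount": 2}])
        out = apply_rna_filters(frame, policy)
        assert (len(out) == 1) == kept


class TestSelectSnpPerGene:
    def test_detailed_most_tissues_wins(self):
        rows = []
        for tissue in ("muscle", "lung", "liver", "ovary", "nerve"):
            rows.append({"position": 1000, "refCount": 10, "altCount": 10, "tissue": tissue})
        for tissue in ("muscle", "lung", "liver"):
            rows.append({"position": 2000, "refCount": 50, "altCount": 50, "tissue": tissue})
        frame = _counts(rows).assign(geneId="G1", parRegion="nonPAR", priorStatus="unknown")
        out = select_snp_per_gene(frame, "detailed")
        assert set(out["position"]) == {1000}
        assert len(out) == 5

    def test_detailed_tie_breaks_on_summed_depth(self):
        rows = []
        for tissue in ("muscle", "lung"):
            rows.append({"position": 1000, "refCount": 80, "altCount": 70, "tissue": tissue})
            rows.append({"position": 2000, "refCount": 60, "altCount": 40, "tissue": tissue})
        frame = _counts(rows).assign(geneId="G1", parRegion="nonPAR", priorStatus="unknown")
        out = select_snp_per_gene(frame, "detailed")
        assert set(out["position"]) == {1000}

    def test_detailed_final_tie_breaks_on_coordinate(self):
        rows = [{"position": p, "refCount": 10, "altCount": 10, "tissue": t}
                for p in (2000, 1000) for t in ("muscle", "lung")]
        frame = _counts(rows).assign(geneId="G1", parRegion="nonPAR", priorStatus="unknown")
        out = select_snp_per_gene(frame, "detailed")
        assert set(out["position"]) == {1000}

    def test_screen_highest_count_wins(self):
        frame = _counts([
            {"position": 1000, "refCount": 100, "altCount": 20},
            {"position": 2000, "refCount": 60, "altCount": 20},
        ]).assign(geneId="G1", parRegion="nonPAR", priorStatus="unknown")
        out = select_snp_per_gene(frame, "screen")
        assert list(out["position"]) == [1000]


class TestAssignXiAllele:
    def test_summed_minor_allele_is_xi(self):
        rows = [{"position": 1000, "refCount": r, "altCount": a, "tissue": t}
                for (r, a, t) in [(90, 10, "muscle"), (95, 5, "lung"), (88, 12, "liver")]]
        out = assign_xi_allele(_counts(rows))
        assert out["xiAllele"].iloc[0] == "alt"

    def test_all_tissue_tie_chooses_alt(self, caplog):
        rows = [{"position": 1000, "refCount": 50, "altCount": 50}]
        with caplog.at_level("WARNING"):
            out = assign_xi_allele(_counts(rows))
        assert out["xiAllele"].iloc[0] == "alt"
        assert any("tie" in r.message for r in caplog.records)

    def test_single_tissue(self):
        out = assign_xi_allele(_counts([{"position": 1000, "refCount": 30, "altCount": 2}]))
        assert out["xiAllele"].iloc[0] == "alt"

    def test_assignment_fixed_across_tissues(self):
        rows = [{"position": 1000, "refCount": 90, "altCount": 10, "tissue": "muscle"},
                {"position": 1000, "refCount": 20, "altCount": 30, "tissue": "lung"}]
        frame = _counts(rows).assign(geneId="G1", parRegion="nonPAR", priorStatus="unknown")
        out = add_xi_columns(build_ae_frame(frame))
        assert set(out["xiAllele"]) == {"alt"}
        assert list(out["xiCount"]) == [10, 30]


class TestExcludeFlaggedSamples:
    def _donor_frame(self, medians):
        rows = []
        for tissue, ae in medians.items():
            for i in range(3):
                rows.append({"donor": "d1", "sample": f"d1:{tissue}", "tissue": tissue,
                             "geneId": f"G{i}", "parRegion": "nonPAR",
                             "priorStatus": "unknown", "aeValue": ae})
        return pd.DataFrame(rows)

    def test_exclusion_list_applied(self):
        frame = self._donor_frame({"muscle": 0.49, "lymphoblasts": 0.48})
        out, log = exclude_flagged_samples(frame, [("d1", "lymphoblasts")])
        assert "lymphoblasts" not in set(out["tissue"])
        assert list(log["reason"]) == ["exclusion list"]

    def test_outlier_rule_flags_low_median_tissue(self):
        """A tissue >0.05 below the donor's median-of-medians is dropped."""
        frame = self._donor_frame({"t1": 0.49, "t2": 0.49, "t3": 0.48, "t4": 0.40})
        out, log = exclude_flagged_samples(frame, outlier_rule=True)
        assert set(out["tissue"]) == {"t1", "t2", "t3"}
        assert list(log["tissue"]) == ["t4"]

    def test_no_rules_retains_everything(self):
        frame = self._donor_frame({"t1": 0.49, "t2": 0.40})
        out, log = exclude_flagged_samples(frame)
        assert len(out) == len(frame)
        assert log.empty


class TestSimulationRecovery:
    def test_gene_ae_matches_expected_minor_fraction(self):
        """Selected-SNP AE recovers 0.5 - pi within binomial error at high depth."""
        rng = np.random.default_rng(7)
        pis = rng.uniform(0.05, 0.45, size=200)
        genes = [GeneSpec(f"G{i:03d}", "escape", round(float(pi), 4),
                          start=3_000_000 + i * 40_000, end=3_020_000 + i * 40_000)
                 for i, pi in enumerate(pis)]
        cfg = SimConfig(n_donors=1, n_nmxci=0, skews=[1.0], tissues=["muscle"],
                        screen_tissue_mix=False, genes=genes, snps_per_gene=1,
                        het_prob=1.0, rna_depth_mean=1000.0,
                        rna_depth_dispersion=1e6, assays=("WES",), seed=13)
        sim = simulate_dataset(cfg)
        ae_frame = build_ae_frame(
            map_counts_to_genes(sim.counts, sim.annotations).pipe(
                select_snp_per_gene, "detailed"))
        truth = sim.truth.genes.set_index("geneId")["xiFraction"]
        merged = ae_frame.set_index("geneId").join(truth)
        depth = merged["usedDepth"]
        sigma = np.sqrt(merged["xiFraction"] * (1 - merged["xiFraction"]) / depth)
        resid = (0.5 - merged["aeValue"]) - merged["xiFraction"]
        assert (resid.abs() <= 3 * sigma + 1e-9).mean() > 0.98

    def test_xi_allele_recovery_on_nmxci_donor(self):
        """With delta=1 and no bias the summed minor allele is the true Xi
        haplotype for every adequately covered, clearly skewed gene."""
        cfg = SimConfig(n_donors=1, n_nmxci=1, tissues=5, screen_tissue_mix=False,
                        n_genes=150, seed=3, snps_per_gene=1, het_prob=1.0,
                        escape_pi_range=(0.15, 0.40), rna_depth_mean=60.0)
        sim = simulate_dataset(cfg)
        ae_frame = compute_ae_table(sim.counts, sim.genotypes, sim.annotations,
                                    FilterPolicy.detailed(), with_xi=True)
        truth_pi = sim.truth.genes.set_index("geneId")["xiFraction"]
        merged = ae_frame.merge(sim.truth.donor_haplotypes,
                                on=["donor", "contig", "position"], how="left")
        per_site = (merged.groupby(["geneId", "position", "xiAllele", "xiAlleleTrue"])
                    .agg(depth=("usedDepth", "sum")).reset_index())
        adequate = per_site[(per_site["depth"] >= 50)
                            & (per_site["geneId"].map(truth_pi) <= 0.40)]
        assert len(adequate) > 50
        assert (adequate["xiAllele"] == adequate["xiAlleleTrue"]).all()
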