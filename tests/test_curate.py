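"""Curation rules: over-estimation, low read count, low power."""

import pandas as pd
import pytest

from xciase.classify import (
    ESCAPE,
    INACTIVE,
    INACTIVE_SINGLE,
    PAR,
    VARIABLE,
    binomial_escape_test,
    classify_genes,
    escape_call_table,
)
from xciase.curate import (
    CurationParams,
    curate_all,
    flag_low_power,
    flag_low_read_count,
    flag_over_estimation,
    min_detectable_xi_fraction,
)
from xciase import ase
from xciase.simulate import GeneSpec, SimConfig, simulate_dataset

PARAMS = CurationParams()


def _calls(rows, gene="G1"):
    frame = pd.DataFrame(rows)
    frame["geneId"] = gene
    if "donor" not in frame.columns:
        frame["donor"] = "d1"
    if "tissue" not in frame.columns:
        frame["tissue"] = [f"t{i}" for i in range(len(frame))]
    if "parRegion" not in frame.columns:
        frame["parRegion"] = "nonPAR"
    frame["xiFraction"] = frame["xiCount"] / frame["usedDepth"]
    frame["aeValue"] = abs(0.5 - frame["xiFraction"])
    frame["pValue"] = [binomial_escape_test(k, n) for k, n in
                       zip(frame["xiCount"], frame["usedDepth"])]
    if "qValue" not in frame.columns:
        frame["qValue"] = frame["pValue"]
    frame["escape"] = frame["qValue"] < 0.01
    return frame


class TestMinDetectableXiFraction:
    def test_shallow_depth_cannot_detect_small_fractions(self):
        # at depth 8, even 2 Xi reads (fraction 0.25) are not significant
        assert binomial_escape_test(2, 8) > 0.01
        assert min_detectable_xi_fraction(8) > 0.25

    def test_deep_site_detects_small_fractions(self):
        f_min = min_detectable_xi_fraction(10_000)
        assert f_min < 0.03
        k = int(f_min * 10_000)
        assert binomial_escape_test(k, 10_000) < 0.01

    def test_fraction_is_smallest_significant(self):
        for depth in (8, 50, 500):
            f_min = min_detectable_xi_fraction(depth)
            k = round(f_min * depth)
            if k <= depth:
                assert binomial_escape_test(k, depth) < 0.01
            assert binomial_escape_test(k - 1, depth) >= 0.01


class TestOverEstimation:
    def test_deep_monoallelic_significant_gene_reclassified(self):
        """xiFraction 0.06 at depth 10^4 is astronomically significant yet
        monoallelic by the AE > 0.4 guideline."""
        calls = _calls([{"xiCount": 600, "usedDepth": 10_000} for _ in range(3)])
        assert calls["escape"].all()
        assert (calls["aeValue"] > 0.4).all()
        outcome = flag_over_estimation(calls, ESCAPE, PARAMS)
        assert outcome is not None
        assert outcome.curated_status == INACTIVE

    def test_genuine_escape_untouched(self):
        calls = _calls([{"xiCount": 3000, "usedDepth": 10_000} for _ in range(3)])
        assert flag_over_estimation(calls, ESCAPE, PARAMS) is None

    def test_requires_a_significant_tissue(self):
        calls = _calls([{"xiCount": 1, "usedDepth": 20} for _ in range(3)])
        assert not calls["escape"].any()
        assert flag_over_estimation(calls, VARIABLE, PARAMS) is None


class TestLowReadCount:
    def _pattern(self, nonsig_xi=3, nonsig_depth=12, n_sig=9):
        rows = [{"xiCount": 30, "usedDepth": 100, "qValue": 1e-6} for _ in range(n_sig)]
        rows.append({"xiCount": nonsig_xi, "usedDepth": nonsig_depth})
        return _calls(rows)

    def test_single_shallow_tissue_rescued(self):
        calls = self._pattern()
        assert int((~calls["escape"]).sum()) == 1
        outcome = flag_low_read_count(calls, VARIABLE, PARAMS)
        assert outcome is not None and outcome.curated_status == ESCAPE

    def test_multiple_nonsignificant_tissues_not_rescued(self):
        rows = [{"xiCount": 30, "usedDepth": 100, "qValue": 1e-6} for _ in range(7)]
        rows += [{"xiCount": 2, "usedDepth": 30} for _ in range(3)]
        assert flag_low_read_count(_calls(rows), VARIABLE, PARAMS) is None

    def test_inconsistent_fraction_not_rescued(self):
        # the non-significant tissue shows essentially no Xi signal
        calls = self._pattern(nonsig_xi=1, nonsig_depth=100)
        assert flag_low_read_count(calls, VARIABLE, PARAMS) is None

    def test_only_fires_on_variable(self):
        assert flag_low_read_count(self._pattern(), INACTIVE, PARAMS) is None


class TestLowPower:
    def test_underpowered_consistent_tissue_rescued(self):
        rows = [{"xiCount": 30, "usedDepth": 100, "qValue": 1e-6} for _ in range(4)]
        rows.append({"xiCount": 2, "usedDepth": 8})  # p ~ 0.017, fraction 0.25
        outcome = flag_low_power(_calls(rows), VARIABLE, PARAMS)
        assert outcome is not None and outcome.curated_status == ESCAPE

    def test_deep_nonsignificant_tissues_block_rescue(self):
        rows = [{"xiCount": 30, "usedDepth": 100, "qValue": 1e-6} for _ in range(4)]
        rows.append({"xiCount": 2, "usedDepth": 1000})  # well powered, clearly inactive
        assert flag_low_power(_calls(rows), VARIABLE, PARAMS) is None

    def test_single_tissue_gene_flag_only(self):
        calls = _calls([{"xiCount": 2, "usedDepth": 8}])
        outcome = flag_low_power(calls, INACTIVE_SINGLE, PARAMS)
        assert outcome is not None
        assert outcome.curated_status == INACTIVE_SINGLE  # unchanged
        assert outcome.rule_applied == "low_power"


def _consensus(status_by_gene):
    return pd.DataFrame({
        "geneId": list(status_by_gene),
        "consensusStatus": list(status_by_gene.values()),
        "nDonors": 1, "nTissuesExpressed": 3, "flags": "",
    })


class TestCurateAll:
    def _planted(self):
        over = _calls([{"xiCount": 600, "usedDepth": 10_000} for _ in range(3)], gene="OVER")
        ok = _calls([{"xiCount": 3000, "usedDepth": 10_000} for _ in range(3)], gene="OK")
        par = _calls([{"xiCount": 4500, "usedDepth": 10_000} for _ in range(3)], gene="PARG")
        par["parRegion"] = "PAR1"
        calls = pd.concat([over, ok, par], ignore_index=True)
        consensus = _consensus({"OVER": ESCAPE, "OK": ESCAPE, "PARG": PAR})
        return consensus, calls

    def test_audit_covers_every_gene(self):
        consensus, calls = self._planted()
        curated, audit = curate_all(consensus, calls)
        assert set(audit["geneId"]) == {"OVER", "OK", "PARG"}
        status = dict(zip(curated["geneId"], curated["consensusStatus"]))
        assert status["OVER"] == INACTIVE
        assert status["OK"] == ESCAPE
        assert status["PARG"] == PAR

    def test_par_never_touched(self):
        consensus, calls = self._planted()
        curated, audit = curate_all(consensus, calls)
        assert audit.loc[audit["geneId"] == "PARG", "rule"].iloc[0] == "none"

    def test_idempotent(self):
        consensus, calls = self._planted()
        once, _ = curate_all(consensus, calls)
        twice, _ = curate_all(once.drop(columns="originalStatus"), calls)
        pd.testing.assert_series_equal(once["consensusStatus"], twice["consensusStatus"])

    def test_rule_order_over_estimation_wins(self):
        # monoallelic everywhere (Xi fraction < 0.1) with one shallow
        # non-significant tissue: the over_estimation verdict takes
        # precedence over any rescue, and the rescues decline monoallelic
        # patterns so precedence is stable under re-runs
        rows = [{"xiCount": 600, "usedDepth": 10_000} for _ in range(9)]
        rows.append({"xiCount": 2, "usedDepth": 25})
        calls = _calls(rows)
        assert flag_low_read_count(calls, VARIABLE, PARAMS) is None
        consensus = _consensus({"G1": VARIABLE})
        curated, audit = curate_all(consensus, calls)
        assert audit["rule"].iloc[0] == "over_estimation"
        assert curated["consensusStatus"].iloc[0] == INACTIVE

    def test_no_rule_fires_identity(self):
        calls = _calls([{"xiCount": 3000, "usedDepth": 10_000} for _ in range(3)])
        consensus = _consensus({"G1": ESCAPE})
        curated, audit = curate_all(consensus, calls)
        assert (audit["rule"] == "none").all()
        assert (curated["consensusStatus"] == curated["originalStatus"]).all()

    def test_planted_over_estimation_genes_in_simulation(self):
        """Deep inactive-leak genes (pi=0.06) are all binomially significant
        but curation reclassifies exactly those genes to inactive."""
        genes = []
        for i in range(5):
            genes.append(GeneSpec(f"LEAK{i}", "inactive", 0.06,
                                  start=3_000_000 + i * 100_000,
                                  end=3_020_000 + i * 100_000))
        for i in range(5):
            genes.append(GeneSpec(f"ESC{i}", "escape", 0.30,
                                  start=10_000_000 + i * 100_000,
                                  end=10_020_000 + i * 100_000))
        cfg = SimConfig(n_donors=1, n_nmxci=1, skews=[1.0], tissues=5,
                        screen_tissue_mix=False, genes=genes, snps_per_gene=1,
                        het_prob=1.0, rna_depth_mean=10_000.0,
                        rna_depth_dispersion=1e6, seed=23)
        sim = simulate_dataset(cfg)
        ae_frame = ase.compute_ae_table(sim.counts, sim.genotypes, sim.annotations,
                                        ase.FilterPolicy.detailed(), with_xi=True)
        calls = escape_call_table(ae_frame)
        _, consensus = classify_genes(calls)
        raw = dict(zip(consensus["geneId"], consensus["consensusStatus"]))
        assert all(raw[f"LEAK{i}"] == ESCAPE for i in range(5))  # inflated by depth
        curated, audit = curate_all(consensus, calls)
        status = dict(zip(curated["geneId"], curated["consensusStatus"]))
        assert all(status[f"LEAK{i}"] == INACTIVE for i in range(5))
        assert all(status[f"ESC{i}"] == ESCAPE for i in range(5))
        changed = set(audit.loc[audit["changed"], "geneId"])
        assert changed == {f"LEAK{i}" for i in range(5)}
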