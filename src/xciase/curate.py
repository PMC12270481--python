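"""Automated, auditable re-classification on top of the binomial calls.

The exact binomial test is only as good as its model: read-count
over-dispersion makes very deep sites significant at biologically
negligible Xi fractions, and shallow sites can miss genuine escape.  This
module applies three curation criteria as explicit rules — the automated
counterpart of a manual review pass:

* ``over_estimation`` — a gene significant somewhere, yet monoallelic in
  every tissue by the empirical allelic-ratio > 0.4 guideline (Xi
  fraction < 0.1), is re-classified inactive: its significance is a
  depth artefact.
* ``low_read_count`` — a variable gene whose single non-significant
  tissue still shows a consistent Xi fraction (>= tau) alongside
  otherwise unanimous significant escape is rescued to escape: one
  shallow tissue should not break an otherwise consistent pattern.
* ``low_power`` — an inactive or variable gene whose non-significant
  tissues are all *underpowered* (their depth cannot detect a Xi
  fraction of tau at the working alpha) while still pointing at escape
  (observed Xi fraction >= tau) is rescued to escape, provided at least
  one tissue is genuinely significant.  Rules re-label; they never invent
  significance.

Rules are applied in a fixed order and at most one rule changes a gene;
every evaluation is logged in an audit table, so curation is idempotent
and every status change is attributable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classify import (
    ESCAPE,
    ESCAPE_TYPE,
    INACTIVE,
    INACTIVE_SINGLE,
    NULL_XI_FRACTION,
    PAR,
    Q_THRESHOLD,
    VARIABLE,
)

logger = logging.getLogger(__name__)

RULE_ORDER = ("over_estimation", "low_read_count", "low_power")


@dataclass(frozen=True)
class CurationParams:
    """Quantitative stand-ins for the manual-review judgement calls."""

    monoallelic_ae_threshold: float = 0.4  # AE above this = mono-allelic (Xi fraction < 0.1)
    tau: float = 0.05  # minimal Xi fraction read as a consistent escape signal
    consistency_tissue_fraction: float = 0.9  # significant-tissue fraction for low_read_count
    alpha: float = Q_THRESHOLD  # working significance proxy for the power bound
    null_p: float = NULL_XI_FRACTION

    def __post_init__(self) -> None:
        if not 0.0 < self.monoallelic_ae_threshold < 0.5:
            raise ValueError("monoallelic_ae_threshold must lie in (0, 0.5)")
        if not self.null_p < self.tau < 0.5:
            raise ValueError(f"tau must lie in ({self.null_p}, 0.5)")


@dataclass(frozen=True)
class CurationOutcome:
    gene_id: str
    original_status: str
    curated_status: str
    rule_applied: str  # rule name or 'none'
    evidence: str = ""

    @property
    def changed(self) -> bool:
        return self.curated_status != self.original_status


def min_detectable_xi_fraction(depth: int, alpha: float = Q_THRESHOLD,
                               null_p: float = NULL_XI_FRACTION) -> float:
    """Smallest Xi fraction detectable at a given read depth.

    Returns the smallest f such that observing ceil(f * depth) Xi reads
    would be significant (upper-tail binomial probability < alpha) —
    i.e. f = k_min / depth for the smallest significant count k_min.
    Returns a value > 1 when no count up to the depth is significant.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    ks = np.arange(0, depth + 1)
    tails = stats.binom.sf(ks - 1, depth, null_p)
    sig = np.nonzero(tails < alpha)[0]
    if sig.size == 0:
        return float(depth + 1) / depth
    return float(ks[sig[0]]) / depth


def _evidence(gene_calls: pd.DataFrame) -> str:
    parts = [
        f"{r.tissue}:xi={r.xiFraction:.3f},q={r.qValue:.2g}{'*' if r.escape else ''}"
        for r in gene_calls.itertuples(index=False)
    ]
    return "; ".join(parts)


def _inactive_label(gene_calls: pd.DataFrame) -> str:
    return INACTIVE if len(gene_calls) > 1 else INACTIVE_SINGLE


def flag_over_estimation(gene_calls: pd.DataFrame, status: str,
                         params: CurationParams) -> CurationOutcome | None:
    """High depth inflated significance: monoallelic everywhere yet significant."""
    gene_id = gene_calls["geneId"].iloc[0]
    if status == PAR or status in INACTIVE_TYPE_SAFE:
        return None
    if not gene_calls["escape"].any():
        return None
    if (gene_calls["aeValue"] > params.monoallelic_ae_threshold).all():
        return CurationOutcome(gene_id, status, _inactive_label(gene_calls),
                               "over_estimation", _evidence(gene_calls))
    return None


INACTIVE_TYPE_SAFE = frozenset({INACTIVE, INACTIVE_SINGLE})


def flag_low_read_count(gene_calls: pd.DataFrame, status: str,
                        params: CurationParams) -> CurationOutcome | None:
    """Variable gene with one shallow non-significant tissue in a
    consistent escape pattern."""
    gene_id = gene_calls["geneId"].iloc[0]
    if status != VARIABLE:
        return None
    non_sig = gene_calls[~gene_calls["escape"]]
    sig = gene_calls[gene_calls["escape"]]
    if len(non_sig) != 1 or sig.empty:
        return None
    if len(sig) / len(gene_calls) < params.consistency_tissue_fraction:
        return None
    if non_sig["xiFraction"].iloc[0] < params.tau:
        return None
    if (sig["xiFraction"] < params.tau).any():
        return None
    if (sig["aeValue"] > params.monoallelic_ae_threshold).all():
        return None  # monoallelic everywhere significant: over-estimation territory
    return CurationOutcome(gene_id, status, ESCAPE, "low_read_count",
                           _evidence(gene_calls))


def flag_low_power(gene_calls: pd.DataFrame, status: str,
                   params: CurationParams) -> CurationOutcome | None:
    """Rescue escape patterns whose non-significant tissues are underpowered."""
    gene_id = gene_calls["geneId"].iloc[0]
    if status not in (INACTIVE, VARIABLE, INACTIVE_SINGLE):
        return None
    if len(gene_calls) == 1:
        # a single underpowered tissue is insufficient evidence; flag only
        row = gene_calls.iloc[0]
        f_min = min_detectable_xi_fraction(int(row["usedDepth"]), params.alpha, params.null_p)
        if not row["escape"] and f_min > params.tau and row["xiFraction"] >= params.tau:
            return CurationOutcome(gene_id, status, status, "low_power",
                                   _evidence(gene_calls))
        return None
    if not gene_calls["escape"].any() or gene_calls["escape"].all():
        return None
    sig = gene_calls[gene_calls["escape"]]
    if (sig["aeValue"] > params.monoallelic_ae_threshold).all():
        return None  # significant tissues are all monoallelic: not an escape pattern
    supports = []
    for row in gene_calls.itertuples(index=False):
        if row.escape:
            supports.append(True)
            continue
        f_min = min_detectable_xi_fraction(int(row.usedDepth), params.alpha, params.null_p)
        supports.append(f_min > params.tau and row.xiFraction >= params.tau)
    if all(supports):
        return CurationOutcome(gene_id, status, ESCAPE, "low_power",
                               _evidence(gene_calls))
    return None


_RULES = {
    "over_estimation": flag_over_estimation,
    "low_read_count": flag_low_read_count,
    "low_power": flag_low_power,
}


def curate_all(
    consensus: pd.DataFrame,
    escape_calls: pd.DataFrame,
    params: CurationParams | None = None,
    rule_order: Sequence[str] = RULE_ORDER,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the curation rules to every classified gene.

    ``consensus`` is the gene-level table from
    :func:`xciase.classify.classify_genes`; ``escape_calls`` the per
    gene x tissue escape-call frame.  Rules run in ``rule_order``; the
    first rule that changes a gene's status wins and later rules are not
    consulted for that gene.  PAR labels are never touched.

    Returns ``(curated consensus, audit)``.  The curated frame carries
    ``originalStatus`` and the final ``consensusStatus``; the audit table
    has one row per gene (geneId, rule, originalStatus, curatedStatus,
    changed, evidence).
    """
    params = params or CurationParams()
    audit_rows = []
    curated_status: dict[str, str] = {}
    calls_by_gene = dict(tuple(escape_calls.groupby("geneId", sort=False)))
    for row in consensus.itertuples(index=False):
        gene_id = row.geneId
        status = row.consensusStatus
        outcome = CurationOutcome(gene_id, status, status, "none")
        gene_calls = calls_by_gene.get(gene_id)
        if status != PAR and gene_calls is not None and not gene_calls.empty:
            for rule in rule_order:
                candidate = _RULES[rule](gene_calls, status, params)
                if candidate is not None:
                    outcome = candidate
                    if candidate.changed:
                        break
        curated_status[gene_id] = outcome.curated_status
        audit_rows.append((gene_id, outcome.rule_applied, outcome.original_status,
                           outcome.curated_status, outcome.changed, outcome.evidence))
    audit = pd.DataFrame(audit_rows, columns=["geneId", "rule", "originalStatus",
                                              "curatedStatus", "changed", "evidence"])
    curated = consensus.copy()
    curated["originalStatus"] = curated["consensusStatus"]
    curated["consensusStatus"] = curated["geneId"].map(curated_status)
    n_changed = int(audit["changed"].sum())
    logger.info("curation re-classified %d of %d genes", n_changed, len(consensus))
    return curated, audit
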