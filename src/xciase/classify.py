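"""Escape calling and cross-tissue / cross-donor XCI status consensus.

Within an nmXCI donor the reads from the inactive X (Xi) at a hetSNP can
be counted directly.  A gene escapes XCI in a tissue when its Xi read
fraction is significantly above the 2.5% technical null: a one-sided
binomial test of ``xiCount`` successes in ``usedDepth`` trials against
``p0 = 0.025``, Benjamini-Hochberg corrected within each tissue (and
donor) separately, significant at ``q < 0.01``.

Across tissues a gene is *escape (across tissues)* when every expressed
tissue is significant, *inactive (across tissues)* when none is,
*variable* when more than one but not all are; genes seen in a single
tissue get the corresponding single-tissue label, and pseudoautosomal
genes are always *PAR*.  Consensus across donors keeps PAR, propagates
unanimous escape/inactive verdicts, and labels any disagreement — within
or between donors — as variable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ValidationError

logger = logging.getLogger(__name__)

NULL_XI_FRACTION = 0.025
Q_THRESHOLD = 0.01

ESCAPE = "escape_across_tissues"
INACTIVE = "inactive_across_tissues"
VARIABLE = "variable"
ESCAPE_SINGLE = "escape_single_tissue"
INACTIVE_SINGLE = "inactive_single_tissue"
PAR = "PAR"

ESCAPE_TYPE = frozenset({ESCAPE, ESCAPE_SINGLE})
INACTIVE_TYPE = frozenset({INACTIVE, INACTIVE_SINGLE})
MULTI_TISSUE = frozenset({ESCAPE, INACTIVE, VARIABLE})

SINGLE_TISSUE_SIGNAL = "single_tissue_signal"


def binomial_escape_test(xi_count: int, used_depth: int,
                         null_p: float = NULL_XI_FRACTION) -> float:
    """Exact one-sided binomial upper-tail probability P(X >= xiCount).

    The null is that at most a fraction ``null_p`` (2.5%) of reads come
    from the inactive X; small p means the Xi contributes significantly
    more — escape.
    """
    if used_depth < 1:
        raise ValidationError("usedDepth must be >= 1")
    if not 0 <= xi_count <= used_depth:
        raise ValidationError(f"xiCount {xi_count} outside [0, {used_depth}]")
    return float(stats.binom.sf(xi_count - 1, used_depth, null_p))


def binomial_escape_test_vec(xi_counts: np.ndarray, depths: np.ndarray,
                             null_p: float = NULL_XI_FRACTION) -> np.ndarray:
    xi = np.asarray(xi_counts)
    d = np.asarray(depths)
    if (d < 1).any() or (xi < 0).any() or (xi > d).any():
        raise ValidationError("invalid xiCount/usedDepth pair")
    return stats.binom.sf(xi - 1, d, null_p)


def fdr_adjust_per_tissue(frame: pd.DataFrame, p_col: str = "pValue",
                          group_cols: Sequence[str] = ("donor", "tissue")) -> pd.Series:
    """Benjamini-Hochberg q-values computed within each tissue separately.

    The adjustment universe is all tested hetSNPs of one donor in one
    tissue; groups are corrected independently of each other.
    """
    p = frame[p_col].to_numpy()
    if ((p < 0) | (p > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    q = np.empty(len(frame), dtype=float)
    group_cols = [c for c in group_cols if c in frame.columns]
    if not group_cols:
        q[:] = multipletests(p, method="fdr_bh")[1] if len(p) else q
    else:
        for _, idx in frame.groupby(group_cols, sort=False).indices.items():
            q[idx] = multipletests(p[idx], method="fdr_bh")[1]
    return pd.Series(q, index=frame.index, name="qValue")


def escape_call_table(ae_xi_frame: pd.DataFrame,
                      null_p: float = NULL_XI_FRACTION,
                      q_threshold: float = Q_THRESHOLD) -> pd.DataFrame:
    """Per gene x tissue escape calls from an Xi-annotated AE frame.

    Input must carry the xiCount/usedDepth columns produced by
    :func:`xciase.ase.add_xi_columns`.  Adds pValue, qValue (BH within
    donor x tissue) and the boolean escape verdict (q strictly below the
    threshold).
    """
    if ae_xi_frame.empty:
        out = ae_xi_frame.copy()
        for col in ("pValue", "qValue"):
            out[col] = pd.Series(dtype=float)
        out["escape"] = pd.Series(dtype=bool)
        return out
    out = ae_xi_frame.copy()
    out["pValue"] = binomial_escape_test_vec(out["xiCount"].to_numpy(),
                                             out["usedDepth"].to_numpy(), null_p)
    out["qValue"] = fdr_adjust_per_tissue(out)
    # strict comparison per the q < 0.01 convention; a threshold of 1
    # degenerates to "every tested site significant"
    out["escape"] = (out["qValue"] < q_threshold) | (q_threshold >= 1.0)
    return out


@dataclass(frozen=True)
class DonorGeneStatus:
    gene_id: str
    donor: str
    status: str
    n_tissues: int
    n_significant: int
    flags: tuple[str, ...] = ()


def classify_within_donor(gene_calls: pd.DataFrame) -> DonorGeneStatus:
    """Across-tissue status of one gene in one donor.

    ``gene_calls`` is the escape-call frame restricted to one (gene,
    donor): one row per expressed tissue.  Significance in exactly one of
    several tissues is read as inactive overall — the variable label
    requires significance in more than one tissue — but is flagged for
    curation review.
    """
    if gene_calls.empty:
        raise ValidationError("classify_within_donor requires >= 1 expressed tissue")
    gene_id = gene_calls["geneId"].iloc[0]
    donor = gene_calls["donor"].iloc[0]
    n = gene_calls["tissue"].nunique()
    n_sig = int(gene_calls["escape"].sum())
    if (gene_calls["parRegion"] != "nonPAR").any():
        return DonorGeneStatus(gene_id, donor, PAR, n, n_sig)
    if n == 1:
        status = ESCAPE_SINGLE if n_sig else INACTIVE_SINGLE
        return DonorGeneStatus(gene_id, donor, status, n, n_sig)
    if n_sig == n:
        return DonorGeneStatus(gene_id, donor, ESCAPE, n, n_sig)
    if n_sig == 0:
        return DonorGeneStatus(gene_id, donor, INACTIVE, n, n_sig)
    if n_sig == 1:
        return DonorGeneStatus(gene_id, donor, INACTIVE, n, n_sig,
                               flags=(SINGLE_TISSUE_SIGNAL,))
    return DonorGeneStatus(gene_id, donor, VARIABLE, n, n_sig)


@dataclass(frozen=True)
class ConsensusCall:
    gene_id: str
    per_donor_status: Mapping[str, str]
    consensus_status: str
    n_tissues_expressed: int
    curation_flags: tuple[str, ...] = ()


def consensus_across_donors(statuses: Sequence[DonorGeneStatus]) -> ConsensusCall:
    """Merge per-donor statuses of one gene into a single consensus.

    PAR stays PAR.  Unanimous escape-type (or inactive-type) verdicts
    propagate, named by the multi-tissue label when at least one donor has
    multi-tissue coverage.  Any donor-level variable call, or
    escape/inactive disagreement among donors, yields variable — the
    label covers both intra- and inter-individual variation.
    """
    if not statuses:
        raise ValidationError("consensus requires >= 1 donor status")
    gene_id = statuses[0].gene_id
    per_donor = {s.donor: s.status for s in statuses}
    n_tissues = sum(s.n_tissues for s in statuses)
    flags = tuple(sorted({f for s in statuses for f in s.flags}))
    labels = set(per_donor.values())
    if PAR in labels:
        consensus = PAR
    elif VARIABLE in labels or (labels & ESCAPE_TYPE and labels & INACTIVE_TYPE):
        consensus = VARIABLE
    elif labels <= ESCAPE_TYPE:
        consensus = ESCAPE if ESCAPE in labels else ESCAPE_SINGLE
    else:
        consensus = INACTIVE if INACTIVE in labels else INACTIVE_SINGLE
    return ConsensusCall(gene_id, per_donor, consensus, n_tissues, flags)


def classify_genes(escape_calls: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-donor and consensus XCI status tables from escape calls.

    Returns ``(per_donor, consensus)``.  ``per_donor`` has one row per
    (gene, donor); ``consensus`` one row per gene with columns geneId,
    consensusStatus, nDonors, nTissuesExpressed, flags.
    """
    donor_statuses: list[DonorGeneStatus] = []
    for _, group in escape_calls.groupby(["geneId", "donor"], sort=True):
        donor_statuses.append(classify_within_donor(group))
    per_donor = pd.DataFrame(
        [(s.gene_id, s.donor, s.status, s.n_tissues, s.n_significant,
          ";".join(s.flags)) for s in donor_statuses],
        columns=["geneId", "donor", "status", "nTissues", "nSignificant", "flags"],
    )
    consensus_rows = []
    by_gene: dict[str, list[DonorGeneStatus]] = {}
    for s in donor_statuses:
        by_gene.setdefault(s.gene_id, []).append(s)
    for gene_id in sorted(by_gene):
        call = consensus_across_donors(by_gene[gene_id])
        consensus_rows.append((gene_id, call.consensus_status, len(call.per_donor_status),
                               call.n_tissues_expressed, ";".join(call.curation_flags)))
    consensus = pd.DataFrame(
        consensus_rows,
        columns=["geneId", "consensusStatus", "nDonors", "nTissuesExpressed", "flags"],
    )
    return per_donor, consensus


def variable_fraction(statuses: Iterable[str]) -> float:
    """Percentage of genes labelled variable, rounded to one decimal."""
    statuses = list(statuses)
    if not statuses:
        return 0.0
    n_var = sum(1 for s in statuses if s == VARIABLE)
    return round(100.0 * n_var / len(statuses), 1)


def compare_classifications(
    set_a: Mapping[str, str],
    set_b: Mapping[str, str],
    label_a: str = "A",
    label_b: str = "B",
) -> tuple[pd.DataFrame, dict]:
    """Transition table between two gene -> status classifications.

    Returns the per-(statusA, statusB) gene counts over the shared genes,
    and a summary with the genes unique to either set and each set's
    variable fraction (as a percentage, one decimal).
    """
    shared = sorted(set(set_a) & set(set_b))
    only_a = sorted(set(set_a) - set(set_b))
    only_b = sorted(set(set_b) - set(set_a))
    pairs = pd.DataFrame(
        [(set_a[g], set_b[g]) for g in shared],
        columns=[f"status_{label_a}", f"status_{label_b}"],
    )
    transitions = (pairs.value_counts().rename("nGenes").reset_index()
                   if len(pairs) else
                   pd.DataFrame(columns=[f"status_{label_a}", f"status_{label_b}", "nGenes"]))
    summary = {
        "n_shared": len(shared),
        f"n_unique_{label_a}": len(only_a),
        f"n_unique_{label_b}": len(only_b),
        f"unique_{label_a}": only_a,
        f"unique_{label_b}": only_b,
        f"variable_fraction_{label_a}": variable_fraction(set_a.values()),
        f"variable_fraction_{label_b}": variable_fraction(set_b.values()),
    }
    return transitions.sort_values("nGenes", ascending=False,
                                   kind="stable").reset_index(drop=True), summary
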