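"""Donor-level detection of non-mosaic X-inactivation (nmXCI).

In a mosaic female, bulk RNA mixes cells inactivating either parental X,
so allelic expression of X-linked genes hovers near 0 (biallelic).  In a
non-mosaic female the same X is inactive in essentially every cell, so
nonPAR genes look nearly monoallelic.  The screen statistic is the
single-sample median AE over nonPAR X genes not previously classified as
variable; a median above 0.475 — under 2.5% of reads from the inactive
allele — calls the donor nmXCI.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SCREEN_THRESHOLD = 0.475


@dataclass(frozen=True)
class DonorSkewCall:
    """Verdict on one sample's XCI skew."""

    donor: str
    sample: str
    tissue: str
    n_genes_used: int
    median_nonpar_ae: float
    standard_error: float
    verdict: str  # 'mosaic' | 'nmXCI' | 'withheld'
    reason: str = ""


def _usable_gene_ae(sample_ae: pd.DataFrame) -> pd.DataFrame:
    """nonPAR genes not previously classified as variable."""
    return sample_ae[(sample_ae["parRegion"] == "nonPAR")
                     & (sample_ae["priorStatus"] != "variable")]


def median_se_bootstrap(values: np.ndarray, n_boot: int = 1000,
                        seed: int = 0) -> float:
    """Nonparametric bootstrap standard error of the median."""
    if len(values) < 2:
        return 0.0
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    idx = rng.integers(0, len(values), size=(n_boot, len(values)))
    return float(np.median(values[idx], axis=1).std(ddof=1))


def screen_donor(
    sample_ae: pd.DataFrame,
    threshold: float = SCREEN_THRESHOLD,
    min_genes: int = 10,
    n_boot: int = 1000,
    seed: int = 0,
) -> DonorSkewCall:
    """Call mosaic vs nmXCI from one sample's gene-level AE table.

    ``sample_ae`` is an AE frame (see :mod:`xciase.ase`) restricted to a
    single donor sample.  PAR genes and genes previously classified as
    variable are excluded before taking the median; the verdict is nmXCI
    iff the median is strictly greater than ``threshold``.  With fewer
    than ``min_genes`` usable genes the verdict is withheld — a median
    over a handful of genes is too unstable to call skew.
    """
    if sample_ae.empty:
        return DonorSkewCall("NA", "NA", "NA", 0, float("nan"), float("nan"),
                             "withheld", "insufficient genes")
    donor = sample_ae["donor"].iloc[0]
    sample = sample_ae["sample"].iloc[0]
    tissue = sample_ae["tissue"].iloc[0]
    usable = _usable_gene_ae(sample_ae)
    values = usable["aeValue"].to_numpy()
    if len(values) < min_genes:
        return DonorSkewCall(donor, sample, tissue, len(values), float("nan"),
                             float("nan"), "withheld", "insufficient genes")
    median = float(np.median(values))
    se = median_se_bootstrap(values, n_boot=n_boot, seed=seed)
    verdict = "nmXCI" if median > threshold else "mosaic"
    return DonorSkewCall(donor, sample, tissue, len(values), median, se, verdict)


def screen_cohort(
    ae_frame: pd.DataFrame,
    threshold: float = SCREEN_THRESHOLD,
    min_genes: int = 10,
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Screen every sample in an AE frame; one designated sample per donor.

    Returns a table sorted by median nonPAR AE (descending) with columns
    donor, sample, tissue, nGenesUsed, medianNonParAE, standardError,
    verdict, reason.
    """
    calls: list[DonorSkewCall] = []
    for i, (_, group) in enumerate(ae_frame.groupby(["donor", "sample"], sort=True)):
        calls.append(screen_donor(group, threshold=threshold, min_genes=min_genes,
                                  n_boot=n_boot, seed=seed + i))
    frame = pd.DataFrame(
        [(c.donor, c.sample, c.tissue, c.n_genes_used, c.median_nonpar_ae,
          c.standard_error, c.verdict, c.reason) for c in calls],
        columns=["donor", "sample", "tissue", "nGenesUsed", "medianNonParAE",
                 "standardError", "verdict", "reason"],
    )
    frame = frame.sort_values("medianNonParAE", ascending=False,
                              kind="stable").reset_index(drop=True)
    n_nmxci = int((frame["verdict"] == "nmXCI").sum())
    logger.info("screen: %d of %d samples called nmXCI", n_nmxci, len(frame))
    return frame


def confirm_multi_tissue(
    donor_ae: pd.DataFrame,
    threshold: float = SCREEN_THRESHOLD,
    min_genes: int = 10,
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[pd.DataFrame, bool]:
    """Per-tissue skew calls for one donor; confirmed iff all retained
    tissues exceed the threshold.

    ``donor_ae`` should already have excluded samples removed (see
    :func:`xciase.ase.exclude_flagged_samples`).  Tissues with a withheld
    verdict (too few genes) do not block confirmation.
    """
    calls = screen_cohort(donor_ae, threshold=threshold, min_genes=min_genes,
                          n_boot=n_boot, seed=seed)
    decided = calls[calls["verdict"] != "withheld"]
    confirmed = (not decided.empty) and bool((decided["verdict"] == "nmXCI").all())
    return calls, confirmed


def plot_ranked_medians(cohort_calls: pd.DataFrame, path: str,
                        threshold: float = SCREEN_THRESHOLD) -> None:
    """Ranked per-sample median nonPAR AE with bootstrap SE bars."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    decided = cohort_calls[cohort_calls["verdict"] != "withheld"].reset_index(drop=True)
    fig, ax = plt.subplots(figsize=(8, 4))
    x = np.arange(len(decided))
    ax.errorbar(x, decided["medianNonParAE"], yerr=decided["standardError"],
                fmt="o", ms=2.5, lw=0.8, color="#444444", ecolor="#bbbbbb")
    ax.axhline(threshold, color="crimson", ls="--", lw=1,
               label=f"nmXCI cutoff ({threshold})")
    ax.set_xlabel("donors, ranked by median nonPAR AE")
    ax.set_ylabel("median nonPAR allelic expression")
    ax.set_ylim(0, 0.52)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
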