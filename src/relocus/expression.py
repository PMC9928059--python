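"""Count normalization, differential expression and deletion-effect estimation.

This stage deliberately replaces a DESeq2-style workflow with a transparent
documented equivalent: median-of-ratios size factors, Welch two-sample tests
on log2(normalized + 1), and Benjamini-Hochberg adjustment.  The biological
thresholds are honored exactly: genes need at least ten reads in total to be
tested, and a gene counts as induced with fold change > 2 at adjusted
p < 0.05.

Deletion effects are summarised as percent reduction,
``100 x (1 - mean_mut / mean_wt)`` on normalized means — the headline effect
measure for enhancer-deletion experiments — and qPCR support is provided via
the comparative-Ct (2^-ddCt) method.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "QpcrMeasurement",
    "prefilter",
    "size_factors",
    "normalize",
    "differential",
    "induced_genes",
    "percent_reduction",
    "remaining_fraction",
    "mrna_share",
    "ddct",
]


@dataclass
class QpcrMeasurement:
    """Triplicate Ct values for a target and a reference (Gapdh-like) gene."""

    sample_id: str
    target_ct: Sequence[float]
    reference_ct: Sequence[float]

    def __post_init__(self) -> None:
        if len(self.target_ct) == 0 or len(self.reference_ct) == 0:
            raise ValueError("triplicate Ct values required for target and reference")
        if min(self.target_ct) <= 0 or min(self.reference_ct) <= 0:
            raise ValueError("Ct values must be positive")

    @property
    def delta_ct(self) -> float:
        # triplicates averaged on the Ct scale before normalization
        return float(np.mean(self.target_ct) - np.mean(self.reference_ct))


def prefilter(counts: pd.DataFrame, min_total: int = 10) -> pd.DataFrame:
    """Keep genes with at least ``min_total`` reads summed over all samples."""
    return counts.loc[counts.sum(axis=1) >= min_total]


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    Per sample: the median over genes of count / geometric mean of that
    gene across samples, using only genes with nonzero counts in every
    sample (their geometric mean is well defined).
    """
    all_pos = (counts > 0).all(axis=1)
    if not all_pos.any():
        raise ValueError(
            "no gene has nonzero counts in every sample; consider adding a "
            "pseudo-count before normalization"
        )
    ref = counts.loc[all_pos]
    log_gmean = np.log(ref).mean(axis=1)
    ratios = np.log(ref).sub(log_gmean, axis=0)
    return np.exp(ratios.median(axis=0)).rename("size_factor")


def normalize(counts: pd.DataFrame) -> tuple[pd.Series, pd.DataFrame]:
    """Size factors plus the normalized (count / factor) matrix."""
    sf = size_factors(counts)
    return sf, counts.div(sf, axis=1)


def differential(
    counts: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
) -> pd.DataFrame:
    """Per-gene Welch test of group B vs group A on log2(normalized + 1).

    Returns a frame indexed by gene with log2_fold_change (B minus A on the
    log scale), p_value, adjusted_p (Benjamini-Hochberg across tested
    genes), normalized group means and percent_change
    ``100 x (mean_B / mean_A - 1)``.
    """
    group_a, group_b = list(group_a), list(group_b)
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least two samples")
    sub = counts[group_a + group_b]
    _, norm = normalize(sub)
    log_a = np.log2(norm[group_a] + 1.0)
    log_b = np.log2(norm[group_b] + 1.0)
    lfc = log_b.mean(axis=1) - log_a.mean(axis=1)
    t, p = stats.ttest_ind(log_b, log_a, axis=1, equal_var=False)
    p = pd.Series(p, index=counts.index)
    p = p.fillna(1.0)  # zero variance in both groups: no evidence of change
    _, padj, _, _ = multipletests(p.values, method="fdr_bh")
    mean_a = norm[group_a].mean(axis=1)
    mean_b = norm[group_b].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = 100.0 * (mean_b / mean_a - 1.0)
    return pd.DataFrame(
        {
            "log2_fold_change": lfc,
            "p_value": p,
            "adjusted_p": pd.Series(padj, index=counts.index),
            "mean_A": mean_a,
            "mean_B": mean_b,
            "percent_change": pct,
        }
    )


def induced_genes(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    tissue: str = "mammary",
    stage_a: str = "p6",
    stages_b: Iterable[str] = ("L1", "L10"),
    genotype: str = "WT",
    fc_threshold: float = 2.0,
    alpha: float = 0.05,
    min_total: int = 10,
) -> set[str]:
    """Genes induced more than ``fc_threshold``-fold (padj < ``alpha``).

    Union over the stage contrasts ``stage_a`` -> each of ``stages_b``
    (positive direction only; fold change > 2 is tested as
    log2 fold change > 1).
    """
    filtered = prefilter(counts, min_total=min_total)
    induced: set[str] = set()
    for stage_b in stages_b:
        cols_a = _select(meta, tissue=tissue, stage=stage_a, genotype=genotype)
        cols_b = _select(meta, tissue=tissue, stage=stage_b, genotype=genotype)
        if not cols_a or not cols_b:
            raise ValueError(
                f"no samples for stage contrast {stage_a!r} vs {stage_b!r} "
                f"in tissue {tissue!r}"
            )
        res = differential(filtered, cols_a, cols_b)
        hit = (res["log2_fold_change"] > np.log2(fc_threshold)) & (
            res["adjusted_p"] < alpha
        )
        induced |= set(res.index[hit])
    return induced


def _select(meta: pd.DataFrame, **conditions) -> list[str]:
    mask = pd.Series(True, index=meta.index)
    for key, value in conditions.items():
        mask &= meta[key] == value
    return list(meta.loc[mask, "sample_id"])


def remaining_fraction(
    counts: pd.DataFrame, gene: str, wt: Sequence[str], mut: Sequence[str]
) -> float:
    """Mutant normalized mean as a fraction of the wild-type mean."""
    wt, mut = list(wt), list(mut)
    if len(wt) < 2 or len(mut) < 2:
        raise ValueError("each group needs at least two samples")
    _, norm = normalize(counts[wt + mut])
    mean_wt = norm.loc[gene, wt].mean()
    mean_mut = norm.loc[gene, mut].mean()
    if mean_wt == 0:
        raise ZeroDivisionError(f"wild-type mean for {gene} is zero")
    return float(mean_mut / mean_wt)


def percent_reduction(
    counts: pd.DataFrame, gene: str, wt: Sequence[str], mut: Sequence[str]
) -> float:
    """``100 x (1 - mutant / wild-type)`` on normalized means.

    Negative values indicate upregulation in the mutant.
    """
    return 100.0 * (1.0 - remaining_fraction(counts, gene, wt, mut))


def mrna_share(
    counts: pd.DataFrame, gene_set: Iterable[str], samples: Sequence[str]
) -> float:
    """Percent of total reads attributed to ``gene_set``, averaged over samples."""
    samples = list(samples)
    sub = counts[samples]
    totals = sub.sum(axis=0)
    if (totals == 0).any():
        raise ValueError("a sample has zero total counts")
    genes = [g for g in gene_set if g in counts.index]
    share = sub.loc[genes].sum(axis=0) / totals
    return float(100.0 * share.mean())


def ddct(wt: QpcrMeasurement, mut: QpcrMeasurement) -> float:
    """Relative expression by the comparative-Ct method.

    ``2 ** -((Ct_target - Ct_ref)_mut - (Ct_target - Ct_ref)_wt)`` with
    triplicates averaged on the Ct scale.
    """
    return float(2.0 ** (-(mut.delta_ct - wt.delta_ct)))
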