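"""Rank-based proteomics statistics for label-free abundance tables.

Implements the comparison workflow used for brain-derived extracellular
vesicle characterization: presence filtering (protein kept when detected in
more than 75% of samples of at least one condition), per-sample low-quantile
imputation of undetected values, trimmed-mean-of-M-values (TMM) scaling
factors, per-sample abundance ranking with condition mean ranks, a rank-sum
differential test with Benjamini-Hochberg adjustment, top-N abundance lists,
and Venn overlap percentages.

Ranks, not normalized intensities, are the comparison currency: per-sample
ranking is invariant to any monotone per-sample transform, which is exactly
what makes the comparison robust to unequal loading between samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AbundanceTable",
    "RankTable",
    "OverlapResult",
    "presence_filter",
    "impute_low_quantile",
    "tmm_factors",
    "rank_proteins",
    "differential_rank_test",
    "top_n_list",
    "overlap_percent",
]


@dataclass
class AbundanceTable:
    """Proteins x samples abundance matrix with condition labels.

    values : DataFrame indexed by protein id, one column per sample;
        missing (undetected) entries are NaN
    conditions : Series mapping sample id -> condition label
    imputed : boolean DataFrame marking entries filled by imputation
    truth : generator ground truth, when the table is synthetic
    """

    values: pd.DataFrame
    conditions: pd.Series
    imputed: Optional[pd.DataFrame] = None
    truth: Optional[dict] = None

    def __post_init__(self) -> None:
        if not self.values.index.is_unique:
            raise ValueError("protein ids must be unique")
        if list(self.conditions.index) != list(self.values.columns):
            self.conditions = self.conditions.reindex(self.values.columns)
        if self.conditions.isna().any():
            raise ValueError("every sample needs a condition label")
        with np.errstate(invalid="ignore"):
            if (self.values.to_numpy() < 0).any():
                raise ValueError("abundances must be non-negative")

    @property
    def detected(self) -> pd.DataFrame:
        """Boolean mask of genuinely detected entries: non-missing values
        that were not filled in by imputation."""
        mask = self.values.notna()
        if self.imputed is not None:
            mask &= ~self.imputed
        return mask

    def samples_of(self, condition: str) -> List[str]:
        sel = self.conditions[self.conditions == condition].index
        if len(sel) == 0:
            raise ValueError(f"condition {condition!r} not present in table")
        return list(sel)


@dataclass
class RankTable:
    """Per-sample abundance ranks (1 = most abundant) and condition means."""

    ranks: pd.DataFrame
    conditions: pd.Series
    condition_mean: pd.DataFrame  # proteins x conditions

    def samples_of(self, condition: str) -> List[str]:
        sel = self.conditions[self.conditions == condition].index
        if len(sel) == 0:
            raise ValueError(f"condition {condition!r} not present in table")
        return list(sel)


@dataclass(frozen=True)
class OverlapResult:
    """Venn overlap of two id lists: percent = shared / union * 100."""

    size_a: int
    size_b: int
    shared: int
    union: int
    percent: int

    def __post_init__(self) -> None:
        if self.shared > min(self.size_a, self.size_b) or self.union < max(self.size_a, self.size_b):
            raise ValueError("inconsistent overlap counts")


def presence_filter(tab: AbundanceTable, min_frac: float = 0.75) -> AbundanceTable:
    """Keep proteins detected in strictly more than ``min_frac`` of the
    samples of at least one condition; row order is preserved."""
    det = tab.detected
    keep = pd.Series(False, index=tab.values.index)
    for cond in tab.conditions.unique():
        cols = tab.samples_of(cond)
        frac = det[cols].mean(axis=1)
        keep |= frac > min_frac
    return AbundanceTable(
        values=tab.values.loc[keep].copy(),
        conditions=tab.conditions.copy(),
        imputed=tab.imputed.loc[keep].copy() if tab.imputed is not None else None,
        truth=tab.truth,
    )


def impute_low_quantile(tab: AbundanceTable, q: float = 0.025) -> AbundanceTable:
    """Fill undetected entries with the sample's ``q`` lower quantile of its
    detected abundances (linear-interpolation quantile, per sample)."""
    if not 0 <= q <= 1:
        raise ValueError("q must be in [0, 1]")
    values = tab.values.copy()
    imputed = values.isna()
    for col in values.columns:
        detected = values[col].dropna()
        if detected.empty:
            raise ValueError(f"sample {col!r} has no detected values to impute from")
        fill = float(np.quantile(detected.to_numpy(), q))
        values[col] = values[col].fillna(fill)
    return AbundanceTable(values=values, conditions=tab.conditions.copy(), imputed=imputed, truth=tab.truth)


def tmm_factors(
    tab: "AbundanceTable | pd.DataFrame",
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    do_weighting: bool = True,
) -> pd.Series:
    """Trimmed-mean-of-M-values effective scaling factors, one per sample.

    The reference sample is the one whose upper-quartile (of the total-sum
    scaled abundances) is closest to the mean upper-quartile. For each sample,
    M (log2 abundance ratio vs the reference, total-sum adjusted) and A
    (mean log2 abundance) are doubly trimmed — ``trim_m`` of the M tails and
    ``trim_a`` of the A tails — and the trimmed fold is 2 to the
    precision-weighted mean of the surviving M values. The returned factor is
    the *effective* size factor, total abundance times the trimmed fold,
    normalized to geometric mean 1: dividing each sample by its factor places
    all samples on a common scale, so a sample loaded at 4x its twin gets a
    factor 4x larger.
    """
    frame = tab.values if isinstance(tab, AbundanceTable) else tab
    if frame.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    x = frame.to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError("TMM requires a complete (imputed) table")
    lib = x.sum(axis=0)
    if np.any(lib <= 0):
        raise ValueError("every sample must have positive total abundance")

    uq = np.array([np.quantile(x[:, j], 0.75) for j in range(x.shape[1])]) / lib
    ref_j = int(np.argmin(np.abs(uq - uq.mean())))
    ref = x[:, ref_j]
    n_ref = lib[ref_j]

    folds = np.ones(x.shape[1])
    for j in range(x.shape[1]):
        obs = x[:, j]
        n_obs = lib[j]
        with np.errstate(divide="ignore", invalid="ignore"):
            log_r = np.log2((obs / n_obs) / (ref / n_ref))
            abs_e = (np.log2(obs / n_obs) + np.log2(ref / n_ref)) / 2.0
            v = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
        fin = np.isfinite(log_r) & np.isfinite(abs_e)
        log_r, abs_e, v = log_r[fin], abs_e[fin], v[fin]
        if log_r.size == 0 or np.max(np.abs(log_r)) < 1e-6:
            continue
        n = log_r.size
        lo_l = math.floor(n * trim_m) + 1
        hi_l = n + 1 - lo_l
        lo_s = math.floor(n * trim_a) + 1
        hi_s = n + 1 - lo_s
        rank_m = stats.rankdata(log_r)
        rank_a = stats.rankdata(abs_e)
        keep = (rank_m >= lo_l) & (rank_m <= hi_l) & (rank_a >= lo_s) & (rank_a <= hi_s)
        if not keep.any():
            continue
        if do_weighting:
            f = np.nansum(log_r[keep] / v[keep]) / np.nansum(1.0 / v[keep])
        else:
            f = np.nanmean(log_r[keep])
        if np.isfinite(f):
            folds[j] = 2.0**f
    factors = lib * folds
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=frame.columns, name="tmm_factor")


def rank_proteins(tab: AbundanceTable) -> RankTable:
    """Rank proteins per sample: 1 = most abundant, ties averaged; undetected
    proteins share the worst tied rank, so rank averages stay comparable
    across samples with different detection depths."""
    values = tab.values
    n_prot = values.shape[0]
    ranks = pd.DataFrame(index=values.index, columns=values.columns, dtype=float)
    for col in values.columns:
        v = values[col].to_numpy(dtype=float)
        det = ~np.isnan(v)
        m = int(det.sum())
        col_ranks = np.empty(n_prot)
        if m:
            col_ranks[det] = stats.rankdata(-v[det], method="average")
        if m < n_prot:
            col_ranks[~det] = (m + 1 + n_prot) / 2.0  # average of ranks m+1..n
        ranks[col] = col_ranks
    cond_mean = pd.DataFrame(index=values.index)
    for cond in tab.conditions.unique():
        cond_mean[cond] = ranks[tab.samples_of(cond)].mean(axis=1)
    return RankTable(ranks=ranks, conditions=tab.conditions.copy(), condition_mean=cond_mean)


def differential_rank_test(
    ranks: RankTable, cond_a: str, cond_b: str, fdr: float = 0.05
) -> pd.DataFrame:
    """Per-protein two-sided rank-sum comparison of per-sample ranks between
    two conditions, Benjamini-Hochberg adjusted.

    Returns a DataFrame (protein_id index) with ``rank_diff`` (mean rank in
    ``cond_a`` minus mean rank in ``cond_b``; negative = more abundant in
    ``cond_a``), ``pvalue``, ``qvalue`` and ``significant`` at the given FDR,
    sorted by q then by |rank_diff| descending. P-values use the asymptotic
    tie-corrected Mann-Whitney statistic without continuity correction:
    ranks are integers so ties across samples are routine (ruling out the
    exact method), and at the group sizes typical here the corrected
    statistic is conservative while the uncorrected one is calibrated at the
    nominal level.
    """
    cols_a = ranks.samples_of(cond_a)
    cols_b = ranks.samples_of(cond_b)
    a = ranks.ranks[cols_a].to_numpy(dtype=float)
    b = ranks.ranks[cols_b].to_numpy(dtype=float)
    diffs = a.mean(axis=1) - b.mean(axis=1)
    pvals = np.empty(len(diffs))
    for i in range(len(diffs)):
        if np.all(a[i] == a[i][0]) and np.all(b[i] == b[i][0]) and a[i][0] == b[i][0]:
            pvals[i] = 1.0
            continue
        res = stats.mannwhitneyu(
            a[i], b[i], alternative="two-sided", method="asymptotic", use_continuity=False
        )
        pvals[i] = res.pvalue
    _, qvals, _, _ = multipletests(pvals, alpha=fdr, method="fdr_bh")
    out = pd.DataFrame(
        {"rank_diff": diffs, "pvalue": pvals, "qvalue": qvals, "significant": qvals < fdr},
        index=ranks.ranks.index,
    )
    out["abs_diff"] = out["rank_diff"].abs()
    out = out.sort_values(["qvalue", "abs_diff"], ascending=[True, False]).drop(columns="abs_diff")
    return out


def top_n_list(ranks: RankTable, condition: str, n: int = 100) -> List[str]:
    """The ``n`` proteins with the smallest condition mean rank (= most
    abundant); ties broken by protein id."""
    if condition not in ranks.condition_mean.columns:
        raise ValueError(f"condition {condition!r} not present")
    if n > ranks.condition_mean.shape[0]:
        raise ValueError("n exceeds the number of proteins")
    mean = ranks.condition_mean[condition]
    order = sorted(mean.index, key=lambda p: (mean[p], p))
    return list(order[:n])


def overlap_percent(list_a: Sequence[str], list_b: Sequence[str]) -> OverlapResult:
    """Venn overlap of two protein lists as an integer percentage of the
    union, truncated to whole percent: 95 shared over a union of 117 prints
    as 81%, 77 over 129 as 59%."""
    set_a, set_b = set(list_a), set(list_b)
    if len(set_a) != len(list_a) or len(set_b) != len(list_b):
        raise ValueError("lists must contain unique ids")
    union = set_a | set_b
    if not union:
        raise ValueError("overlap of two empty lists is undefined")
    shared = len(set_a & set_b)
    percent = math.floor(shared / len(union) * 100)
    return OverlapResult(
        size_a=len(set_a), size_b=len(set_b), shared=shared, union=len(union), percent=percent
    )
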