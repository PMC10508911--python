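"""Lysogeny prevalence and abundance analytics over a MAG collection.

Lysogen prevalence is stratified by MAG completeness (incomplete bins
lose prophages to contig dropout, so raw prevalence understates the truth)
and by bacterial family, with minimum-group-size rules before a group is
reported as included.  Infant MAGs are categorized Early/Late from their
relative-abundance trajectory across the four infant timepoints.
Correlation and two-sample comparisons use Spearman's rank correlation
and the Mann-Whitney/Wilcoxon rank-sum test; per-family abundance
comparisons are adjusted with Benjamini-Hochberg FDR.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_BINS: tuple[tuple[float, float], ...] = ((70, 85), (85, 95), (95, 100))
EARLY_TIMEPOINTS = ("3w", "3m")
LATE_TIMEPOINTS = ("6m", "12m")
INFANT_TIMEPOINTS = EARLY_TIMEPOINTS + LATE_TIMEPOINTS


def completeness_bin_labels(
    bins: Sequence[tuple[float, float]] = DEFAULT_BINS,
) -> list[str]:
    labels = [f"{int(bins[0][0])}-{int(bins[0][1])}"]
    for lo, hi in bins[1:-1]:
        labels.append(f"{int(lo) + 1}-{int(hi)}")
    labels.append(f">{int(bins[-1][0])}")
    return labels


def bin_by_completeness(
    completeness: Sequence[float] | pd.Series,
    bins: Sequence[tuple[float, float]] = DEFAULT_BINS,
) -> pd.Series:
    """Assign each MAG to a completeness bin.

    Bins are half-open ``(lo, hi]`` except the first, which is closed
    ``[lo, hi]``; with the defaults this yields the contiguous cover
    [70, 85], (85, 95], (95, 100] labelled ``70-85``, ``86-95``, ``>95``.
    Values outside the binned range raise.
    """
    values = pd.Series(completeness, dtype=float)
    lo_all, hi_all = bins[0][0], bins[-1][1]
    if ((values < lo_all) | (values > hi_all)).any():
        bad = values[(values < lo_all) | (values > hi_all)].iloc[0]
        raise ValueError(f"completeness {bad} outside [{lo_all}, {hi_all}]")
    edges = [bins[0][0]] + [hi for _, hi in bins]
    labels = completeness_bin_labels(bins)
    out = pd.cut(values, bins=edges, labels=labels, include_lowest=True)
    return out.astype(str).rename("completeness_bin")


def prevalence_by_group(
    mags: pd.DataFrame,
    by: str | list[str],
    min_n: int = 1,
    lysogen_col: str = "is_lysogen",
) -> pd.DataFrame:
    """Per-group lysogen prevalence with a minimum-group-size rule.

    Groups with fewer than ``min_n`` MAGs are still reported but flagged
    ``included=False``.  Prevalence is n_lysogens / n_mags.
    """
    by = [by] if isinstance(by, str) else list(by)
    grouped = mags.groupby(by, dropna=False, observed=True)[lysogen_col]
    out = grouped.agg(n_mags="size", n_lysogens="sum").reset_index()
    out["n_lysogens"] = out["n_lysogens"].astype(int)
    out["prevalence"] = out["n_lysogens"] / out["n_mags"]
    out["included"] = out["n_mags"] >= min_n
    return out


def classify_early_late(
    abundance: pd.DataFrame,
    early: Sequence[str] = EARLY_TIMEPOINTS,
    late: Sequence[str] = LATE_TIMEPOINTS,
) -> pd.Series:
    """Categorize infant MAGs as Early / Late / Unassigned.

    ``abundance`` is a wide table indexed by mag_id with one column per
    infant timepoint (copies per million; NaN for missing samples).  A MAG
    is Early iff its mean abundance over the available early timepoints
    strictly exceeds the mean over the available late ones, Late iff
    strictly less, and Unassigned on an exact tie or when either side has
    no data.  Swapping the two column groups flips Early and Late.
    """
    early_cols = [c for c in early if c in abundance.columns]
    late_cols = [c for c in late if c in abundance.columns]
    early_mean = abundance[early_cols].mean(axis=1, skipna=True) if early_cols else \
        pd.Series(np.nan, index=abundance.index)
    late_mean = abundance[late_cols].mean(axis=1, skipna=True) if late_cols else \
        pd.Series(np.nan, index=abundance.index)
    out = pd.Series("Unassigned", index=abundance.index, name="cohort_group")
    valid = early_mean.notna() & late_mean.notna()
    out[valid & (early_mean > late_mean)] = "Early"
    out[valid & (early_mean < late_mean)] = "Late"
    return out


def spearman_correlation(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation on mid-ranks with a t-distribution p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("x and y must have equal length >= 3")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def ranksum_test(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney/Wilcoxon rank-sum test.

    Uses exact enumeration for small samples (n_a + n_b <= 12, no ties)
    and the tie-corrected normal approximation otherwise.  Returns the U
    statistic of the first sample and the two-sided p-value.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([a, b])
    has_ties = len(np.unique(combined)) < len(combined)
    method = "exact" if (a.size + b.size <= 12 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def abundance_comparison(
    mags: pd.DataFrame,
    min_per_arm: int = 5,
    family_col: str = "family",
    lysogen_col: str = "is_lysogen",
    abundance_col: str = "abundance",
) -> pd.DataFrame:
    """Per-family lysogen vs non-lysogen abundance rank-sum tests.

    Families with fewer than ``min_per_arm`` MAGs in either arm are
    reported with ``included=False`` and no test; tested families get a
    two-sided rank-sum p and a Benjamini-Hochberg adjusted p across the
    tested families.
    """
    rows = []
    for family, group in mags.groupby(family_col, observed=True):
        lys = group.loc[group[lysogen_col].astype(bool), abundance_col].dropna()
        non = group.loc[~group[lysogen_col].astype(bool), abundance_col].dropna()
        row = {"family": family, "n_lysogens": len(lys), "n_non_lysogens": len(non),
               "included": len(lys) >= min_per_arm and len(non) >= min_per_arm,
               "statistic": np.nan, "p_value": np.nan}
        if row["included"]:
            row["statistic"], row["p_value"] = ranksum_test(lys, non)
        rows.append(row)
    out = pd.DataFrame(rows, columns=["family", "n_lysogens", "n_non_lysogens",
                                      "included", "statistic", "p_value"])
    out["p_adjusted"] = np.nan
    tested = out["included"] & out["p_value"].notna()
    if tested.any():
        out.loc[tested, "p_adjusted"] = stats.false_discovery_control(
            out.loc[tested, "p_value"].to_numpy(), method="bh"
        )
    return out
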