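"""Retention analysis: expression summarization, binning, extreme-decile
contrast, stratified retention and functional-category enrichment.

The pipeline goes: probe-level medians (if probe rows are present) ->
between-array normalization -> per-gene level = log2 of the median signal
across conditions -> assign each ohnologon the level of one randomly
chosen member -> fixed-interval bins of retention frequency, with
small bins excluded.  All stages log record counts so that
records in = records out + logged exclusions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

logger = logging.getLogger("costex")

__all__ = [
    "probe_median",
    "normalize_between_arrays",
    "summarize_expression",
    "assign_ohnologon_expression",
    "bin_retention",
    "DecileComparison",
    "extreme_decile_comparison",
    "stratified_retention",
    "category_enrichment",
    "lowess_curve",
    "two_by_two_pvalue",
]


def _condition_columns(matrix: pd.DataFrame) -> list:
    reserved = {"gene_id", "probe_id"}
    return [c for c in matrix.columns if c not in reserved]


def probe_median(matrix: pd.DataFrame) -> pd.DataFrame:
    """Collapse probe-level rows to one row per gene by per-condition
    median.  ``matrix`` needs a ``gene_id`` column; any ``probe_id``
    column is dropped.  Raises if a gene ends up with no probe rows
    (possible when ``gene_id`` values are NA)."""
    if "gene_id" not in matrix.columns:
        raise ValueError("probe-level matrix must have a 'gene_id' column")
    if matrix["gene_id"].isna().any():
        bad = matrix.index[matrix["gene_id"].isna()][0]
        raise ValueError(f"probe row {bad} has no gene assigned")
    cols = _condition_columns(matrix)
    out = matrix.groupby("gene_id", sort=True)[cols].median().reset_index()
    logger.info("probe_median: %d probe rows -> %d genes", len(matrix), len(out))
    return out


def normalize_between_arrays(matrix: pd.DataFrame, method: str = "quantile") -> pd.DataFrame:
    """Normalize condition columns across arrays.

    ``method`` is one of ``none``, ``scale`` (rescale every column to the
    common median) or ``quantile`` (all columns share the mean sorted
    profile; tied values receive the mean of their quantile values).
    """
    cols = _condition_columns(matrix)
    if len(cols) < 2:
        raise ValueError("need at least 2 condition columns to normalize")
    values = matrix[cols].to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise TypeError("non-numeric cells in expression matrix")
    out = matrix.copy()
    if method == "none":
        return out
    if method == "scale":
        col_medians = np.median(values, axis=0)
        if np.any(col_medians <= 0):
            raise ValueError("non-positive column median; cannot scale-normalize")
        target = np.exp(np.mean(np.log(col_medians)))
        out[cols] = values * (target / col_medians)
        return out
    if method == "quantile":
        ref = np.sort(values, axis=0).mean(axis=1)
        norm = np.empty_like(values, dtype=float)
        for j in range(values.shape[1]):
            col = values[:, j]
            order = np.argsort(col, kind="stable")
            assigned = np.empty(len(col))
            assigned[order] = ref
            # ties share the mean of the quantile values they span
            norm[:, j] = pd.Series(assigned).groupby(pd.Series(col)).transform("mean").to_numpy()
        out[cols] = norm
        return out
    raise ValueError(f"unknown normalization method {method!r}")


def summarize_expression(matrix: pd.DataFrame, floor: Optional[float | str] = None) -> pd.Series:
    """Per-gene expression level: log2 of the median signal across
    conditions.

    Zero or negative signals raise unless ``floor`` is set: a number
    replaces smaller signals, ``"auto"`` uses the smallest positive
    observed signal.  Returns a Series indexed by ``gene_id``.
    """
    cols = _condition_columns(matrix)
    values = matrix[cols].to_numpy(dtype=float)
    if floor == "auto":
        positive = values[values > 0]
        if positive.size == 0:
            raise ValueError("no positive signals to derive a floor from")
        floor = float(positive.min())
    if floor is not None:
        values = np.maximum(values, float(floor))
    if np.any(values <= 0):
        raise ValueError(
            "non-positive signal encountered; set a pseudo-signal floor "
            "to take log2"
        )
    levels = np.log2(np.median(values, axis=1))
    index = matrix["gene_id"] if "gene_id" in matrix.columns else matrix.index
    return pd.Series(levels, index=pd.Index(index, name="gene_id"), name="level")


def assign_ohnologon_expression(
    records: pd.DataFrame,
    levels: pd.Series,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Assign each ohnologon the level of one randomly chosen member.

    ``records`` needs ``ohnologon_id`` and ``members`` (comma-separated
    gene IDs).  Members without a level are not eligible; records whose
    members all lack levels are dropped, with the count logged.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    member_lists = records["members"].str.split(",")
    picked = np.full(len(records), np.nan)
    for i, members in enumerate(member_lists):
        eligible = [levels[m] for m in members if m in levels.index]
        if eligible:
            picked[i] = eligible[int(rng.integers(len(eligible)))]
    keep = ~np.isnan(picked)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("assign_ohnologon_expression: dropped %d records with no leveled member", n_dropped)
    out = records.loc[keep].copy()
    out["level"] = picked[keep]
    return out


def _bin_index(levels: np.ndarray, interval: float) -> np.ndarray:
    return np.floor(levels / interval).astype(int)


def bin_retention(
    records: pd.DataFrame,
    interval: float,
    min_count: int = 30,
    level_col: str = "level",
    retained_col: str = "retained",
) -> pd.DataFrame:
    """Group records into half-open fixed-interval bins of ``level`` and
    compute the retention frequency per bin.

    Bins are ``[lo, lo + interval)`` anchored at integer multiples of the
    interval.  Bins with fewer than ``min_count`` records are flagged
    ``included=False`` (and logged) rather than silently dropped, so
    counts are conserved.
    """
    if interval <= 0:
        raise ValueError("interval must be positive")
    if len(records) == 0:
        return pd.DataFrame(columns=["lo", "hi", "n", "n_retained", "retention", "included"])
    levels = records[level_col].to_numpy(dtype=float)
    retained = records[retained_col].to_numpy(dtype=bool)
    idx = _bin_index(levels, interval)
    grouped = pd.DataFrame({"idx": idx, "retained": retained}).groupby("idx")["retained"]
    summary = grouped.agg(n="size", n_retained="sum").reset_index()
    summary["lo"] = summary["idx"] * interval
    summary["hi"] = (summary["idx"] + 1) * interval
    summary["retention"] = summary["n_retained"] / summary["n"]
    summary["included"] = summary["n"] >= min_count
    n_excluded = int(summary.loc[~summary["included"], "n"].sum())
    logger.info(
        "bin_retention: %d records in %d bins; %d records in %d excluded bins",
        len(records), len(summary), n_excluded, int((~summary["included"]).sum()),
    )
    return summary[["lo", "hi", "n", "n_retained", "retention", "included"]].sort_values("lo").reset_index(drop=True)


def two_by_two_pvalue(table: np.ndarray) -> float:
    """P-value for a 2x2 contingency table: Pearson chi-square without
    continuity correction, or Fisher's exact test when any expected count
    falls below 5 (including degenerate margins)."""
    table = np.asarray(table, dtype=float)
    total = table.sum()
    if total == 0:
        return 1.0
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
    if expected.min() < 5:
        return float(scipy.stats.fisher_exact(table.astype(int))[1])
    _, p, _, _ = scipy.stats.chi2_contingency(table, correction=False)
    return float(p)


@dataclass(frozen=True)
class DecileComparison:
    """Retention contrast between the extreme expression deciles."""

    freq_bottom: float
    freq_top: float
    fold: float
    p: float
    n_per_decile: int
    fold_is_infinite: bool = False


def extreme_decile_comparison(
    records: pd.DataFrame,
    level_col: str = "level",
    retained_col: str = "retained",
    id_col: str = "ohnologon_id",
) -> DecileComparison:
    """Compare retention between the 10% least and 10% most expressed
    records.  Ties in level are broken by a stable sort on the ID column
    for reproducibility."""
    if len(records) < 20:
        raise ValueError("need at least 20 records for a decile comparison")
    ordered = records.sort_values([level_col, id_col], kind="mergesort")
    n_dec = len(ordered) // 10
    bottom = ordered.head(n_dec)[retained_col].to_numpy(dtype=bool)
    top = ordered.tail(n_dec)[retained_col].to_numpy(dtype=bool)
    freq_bottom = float(bottom.mean())
    freq_top = float(top.mean())
    infinite = freq_bottom == 0 and freq_top > 0
    if infinite:
        fold = float("inf")
    elif freq_bottom == 0:
        fold = float("nan")
    else:
        fold = freq_top / freq_bottom
    table = np.array(
        [
            [bottom.sum(), n_dec - bottom.sum()],
            [top.sum(), n_dec - top.sum()],
        ]
    )
    return DecileComparison(
        freq_bottom=freq_bottom,
        freq_top=freq_top,
        fold=fold,
        p=two_by_two_pvalue(table),
        n_per_decile=n_dec,
        fold_is_infinite=infinite,
    )


def stratified_retention(
    records: pd.DataFrame,
    strata: pd.DataFrame,
    n_quantiles: int = 4,
    level_col: str = "level",
    retained_col: str = "retained",
    id_col: str = "ohnologon_id",
) -> pd.DataFrame:
    """Within each stratum, split records into ``n_quantiles`` equal-size
    (+-1) groups by level and compute retention per group.

    ``strata`` maps ``id_col`` to a ``stratum`` label; records may map to
    several strata (one row per membership) or none.  Strata with fewer
    records than ``n_quantiles`` are skipped with a log entry.
    """
    merged = records.merge(strata, on=id_col)
    rows = []
    for stratum, group in merged.groupby("stratum"):
        if len(group) < n_quantiles:
            logger.info("stratified_retention: skipping stratum %r with %d records", stratum, len(group))
            continue
        ordered = group.sort_values([level_col, id_col], kind="mergesort")
        for q, chunk in enumerate(np.array_split(ordered.index.to_numpy(), n_quantiles), start=1):
            sub = ordered.loc[chunk]
            rows.append(
                {
                    "stratum": stratum,
                    "quantile": q,
                    "n": len(sub),
                    "retention": float(sub[retained_col].mean()),
                    "mean_level": float(sub[level_col].mean()),
                }
            )
    return pd.DataFrame(rows, columns=["stratum", "quantile", "n", "retention", "mean_level"])


def category_enrichment(
    records: pd.DataFrame,
    membership: pd.DataFrame,
    min_genes: int = 400,
    overlap: float = 0.90,
    level_col: str = "level",
    retained_col: str = "retained",
    id_col: str = "ohnologon_id",
) -> pd.DataFrame:
    """Per-category retention and expression contrasted with all other
    records.

    ``membership`` has columns ``category`` and ``id_col``.  Categories
    with ``min_genes`` or fewer members are dropped.  Redundant
    categories -- pairwise overlap ``shared / min(sizes)`` above
    ``overlap`` -- are resolved by keeping the category with the larger
    gene list.  For each survivor the result reports retention of members
    vs. non-members with a 2x2 chi-square/Fisher p-value, and mean level
    of members vs. non-members with a two-sample t-test p-value.
    """
    ids = records[id_col]
    sets = {
        cat: frozenset(sub[id_col]) & frozenset(ids)
        for cat, sub in membership.groupby("category")
    }
    sets = {cat: s for cat, s in sets.items() if len(s) > min_genes}
    ordered = sorted(sets, key=lambda c: (-len(sets[c]), c))
    kept = []
    for cat in ordered:
        redundant = any(
            len(sets[cat] & sets[other]) / min(len(sets[cat]), len(sets[other])) > overlap
            for other in kept
        )
        if redundant:
            logger.info("category_enrichment: dropping %r as redundant", cat)
        else:
            kept.append(cat)
    rows = []
    for cat in sorted(kept):
        member = records[id_col].isin(sets[cat]).to_numpy()
        ret = records[retained_col].to_numpy(dtype=bool)
        lev = records[level_col].to_numpy(dtype=float)
        table = np.array(
            [
                [ret[member].sum(), member.sum() - ret[member].sum()],
                [ret[~member].sum(), (~member).sum() - ret[~member].sum()],
            ]
        )
        t_p = scipy.stats.ttest_ind(lev[member], lev[~member]).pvalue
        rows.append(
            {
                "category": cat,
                "n": int(member.sum()),
                "retention": float(ret[member].mean()),
                "retention_others": float(ret[~member].mean()),
                "p_retention": two_by_two_pvalue(table),
                "mean_level": float(lev[member].mean()),
                "mean_level_others": float(lev[~member].mean()),
                "p_level": float(t_p),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "category", "n", "retention", "retention_others", "p_retention",
            "mean_level", "mean_level_others", "p_level",
        ],
    )


def lowess_curve(x, y, frac: float = 0.5):
    """Locally weighted regression smoother, for visual aid only.

    Returns ``(xs, ys)`` sorted by x.  With fewer than 5 points the input
    is passed through unchanged with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 5:
        warnings.warn("fewer than 5 points; lowess skipped", stacklevel=2)
        order = np.argsort(x, kind="stable")
        return x[order], y[order]
    smoothed = sm.nonparametric.lowess(y, x, frac=frac, return_sorted=True)
    return smoothed[:, 0], smoothed[:, 1]
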