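"""Expression-divergence metrics for ohnolog pairs, Ka-expression
correlation, and the heterozygous-KO fitness-by-expression analysis."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd
import scipy.stats

from .retention import _bin_index

logger = logging.getLogger("costex")

__all__ = [
    "pearson_divergence",
    "euclidean_divergence",
    "pair_divergence_table",
    "correlate_with_expression",
    "KOBinResult",
    "ko_fitness_by_expression",
]


def pearson_divergence(profile_a, profile_b) -> float:
    """Pearson correlation between the two expression profiles of an
    ohnolog pair.  Returns NaN (logged) when either profile is constant,
    where the coefficient is undefined."""
    a = np.asarray(profile_a, dtype=float)
    b = np.asarray(profile_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"profile lengths differ: {a.shape} vs {b.shape}")
    if a.size < 2:
        raise ValueError("profiles need at least 2 conditions")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        logger.info("pearson_divergence: constant profile, correlation undefined")
        return float("nan")
    return float(scipy.stats.pearsonr(a, b).statistic)


def euclidean_divergence(profile_a, profile_b) -> float:
    """Euclidean distance between the two expression profiles of a pair."""
    a = np.asarray(profile_a, dtype=float)
    b = np.asarray(profile_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"profile lengths differ: {a.shape} vs {b.shape}")
    return float(np.linalg.norm(a - b))


def pair_divergence_table(
    pairs: pd.DataFrame,
    matrix: pd.DataFrame,
    log2: bool = True,
) -> pd.DataFrame:
    """Both divergence metrics for every pair.

    ``pairs`` needs columns ``pair_id``, ``gene1``, ``gene2``; ``matrix``
    is a gene-level signal table with a ``gene_id`` column.  Profiles are
    log2-transformed by default.  Pairs with a missing member are dropped
    (logged).
    """
    cols = [c for c in matrix.columns if c != "gene_id"]
    profiles = matrix.set_index("gene_id")[cols]
    values = profiles.to_numpy(dtype=float)
    if log2:
        values = np.log2(values)
    lookup = {g: i for i, g in enumerate(profiles.index)}
    rows = []
    n_dropped = 0
    for rec in pairs.itertuples(index=False):
        ia, ib = lookup.get(rec.gene1), lookup.get(rec.gene2)
        if ia is None or ib is None:
            n_dropped += 1
            continue
        rows.append(
            {
                "pair_id": rec.pair_id,
                "pearson": pearson_divergence(values[ia], values[ib]),
                "euclidean": euclidean_divergence(values[ia], values[ib]),
            }
        )
    if n_dropped:
        logger.info("pair_divergence_table: dropped %d pairs with missing profiles", n_dropped)
    return pd.DataFrame(rows, columns=["pair_id", "pearson", "euclidean"])


def correlate_with_expression(values, levels) -> Tuple[float, float]:
    """Pearson correlation (r, two-sided p) between a per-gene/per-pair
    quantity and expression level, over complete observations."""
    v = np.asarray(values, dtype=float)
    l = np.asarray(levels, dtype=float)
    if v.shape != l.shape:
        raise ValueError("values and levels must have equal length")
    ok = ~(np.isnan(v) | np.isnan(l))
    if ok.sum() < 3:
        raise ValueError("need at least 3 complete observations")
    res = scipy.stats.pearsonr(v[ok], l[ok])
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class KOBinResult:
    """Binned heterozygous-KO fitness summary."""

    bins: pd.DataFrame          # lo, hi, n, mean_fitness, ci_low, ci_high
    r: float                    # Pearson r of min-fitness vs. level
    p: float
    n_genes: int
    n_dropped: int


def ko_fitness_by_expression(
    table: pd.DataFrame,
    levels: pd.Series,
    interval: float = 0.5,
    min_count: int = 30,
    ci: str = "normal",
    n_boot: int = 1000,
    seed: Optional[int] = None,
) -> KOBinResult:
    """Bin per-gene minimal KO fitness by expression level.

    Each gene's fitness is summarized as the minimum across conditions.
    Genes are grouped into fixed-interval level bins (same anchoring as
    the retention binning engine); bins below ``min_count`` genes are
    flagged excluded.  The 95% CI per bin is mean +- 1.96*sd/sqrt(n) by
    default, or a percentile bootstrap with ``ci="bootstrap"``.
    """
    per_gene = table.groupby("gene_id")["fitness"].min()
    merged = pd.DataFrame({"fitness": per_gene}).join(levels.rename("level"), how="left")
    n_dropped = int(merged["level"].isna().sum())
    if n_dropped:
        logger.info("ko_fitness_by_expression: dropped %d genes without a level", n_dropped)
    merged = merged.dropna(subset=["level"])
    idx = _bin_index(merged["level"].to_numpy(), interval)
    rng = np.random.default_rng(seed)
    rows = []
    for b, sub in merged.groupby(idx):
        fit = sub["fitness"].to_numpy()
        mean = float(fit.mean())
        if ci == "bootstrap" and len(fit) > 1:
            boots = rng.choice(fit, size=(n_boot, len(fit)), replace=True).mean(axis=1)
            lo_ci, hi_ci = np.percentile(boots, [2.5, 97.5])
        else:
            half = 1.96 * fit.std(ddof=1) / np.sqrt(len(fit)) if len(fit) > 1 else 0.0
            lo_ci, hi_ci = mean - half, mean + half
        rows.append(
            {
                "lo": b * interval,
                "hi": (b + 1) * interval,
                "n": len(fit),
                "mean_fitness": mean,
                "ci_low": float(lo_ci),
                "ci_high": float(hi_ci),
                "included": len(fit) >= min_count,
            }
        )
    bins = pd.DataFrame(rows).sort_values("lo").reset_index(drop=True)
    if len(merged) >= 3 and merged["fitness"].nunique() > 1 and merged["level"].nunique() > 1:
        r, p = correlate_with_expression(merged["fitness"], merged["level"])
    else:
        r, p = float("nan"), float("nan")
    return KOBinResult(bins=bins, r=r, p=p, n_genes=len(merged), n_dropped=n_dropped)
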