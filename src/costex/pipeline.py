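"""End-to-end orchestration: generate -> simulate -> analyze.

Thin drivers that connect the generator, the loss simulator and the
analysis stages on in-memory tables; the CLI wraps these with file I/O.
Every stochastic stage receives its own child of the master seed.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from . import io as cio
from . import metrics, retention
from .synth import GeneratorConfig, generate_dataset

logger = logging.getLogger("costex")

__all__ = [
    "OHNOLOGON_SCHEMA",
    "ANNOTATION_SCHEMA",
    "KA_SCHEMA",
    "KO_SCHEMA",
    "MODEL_SCHEMA",
    "analyze_retention",
    "analyze_divergence",
    "analyze_ko",
    "run_end_to_end",
]

OHNOLOGON_SCHEMA = cio.TableSchema(
    columns={"ohnologon_id": "str", "wgd_level": "str", "members": "str", "retained": "bool"},
    key="ohnologon_id",
)
ANNOTATION_SCHEMA = cio.TableSchema(
    columns={"gene_id": "str", "ohnologon_id": "str", "categories": "str",
             "phylo_group": "str", "complex": "bool"},
    key="gene_id",
)
KA_SCHEMA = cio.TableSchema(
    columns={"pair_id": "str", "gene1": "str", "gene2": "str", "ka": "float"},
    key="pair_id",
)
KO_SCHEMA = cio.TableSchema(
    columns={"gene_id": "str", "condition": "str", "fitness": "float"}
)
MODEL_SCHEMA = cio.TableSchema(
    columns={"ohnologon_id": "str", "X0": "float"},
    key="ohnologon_id",
)


def _levels_from_matrix(expression: pd.DataFrame, normalize: str, floor) -> pd.Series:
    matrix = expression
    if "probe_id" in matrix.columns:
        matrix = retention.probe_median(matrix)
    if normalize != "none":
        matrix = retention.normalize_between_arrays(matrix, method=normalize)
    return retention.summarize_expression(matrix, floor=floor)


def analyze_retention(
    expression: pd.DataFrame,
    ohnologons: pd.DataFrame,
    annotation: Optional[pd.DataFrame] = None,
    interval: float = 0.2,
    min_bin: int = 30,
    seed: Optional[int] = None,
    normalize: str = "none",
    floor=None,
    min_category: int = 400,
    lowess_frac: float = 0.5,
) -> Dict[str, object]:
    """Full retention analysis on one WGD level's ohnologon table.

    Returns a dict with the leveled records, the bin table, the extreme
    decile comparison, a lowess curve over included bins, and -- when an
    annotation is supplied -- complex/phylogeny-stratified tables and the
    functional-category enrichment table.
    """
    levels = _levels_from_matrix(expression, normalize, floor)
    records = retention.assign_ohnologon_expression(ohnologons, levels, seed=seed)
    bins = retention.bin_retention(records, interval, min_count=min_bin)
    deciles = retention.extreme_decile_comparison(records)
    included = bins[bins["included"]]
    if len(included) >= 5:
        mid = (included["lo"] + included["hi"]) / 2.0
        xs, ys = retention.lowess_curve(mid, included["retention"], frac=lowess_frac)
        lowess = pd.DataFrame({"level": xs, "retention_smooth": ys})
    else:
        lowess = pd.DataFrame(columns=["level", "retention_smooth"])
    out: Dict[str, object] = {
        "records": records,
        "bins": bins,
        "deciles": deciles,
        "lowess": lowess,
    }
    if annotation is not None:
        ohno_ann = annotation.drop_duplicates("ohnologon_id")
        complex_strata = pd.DataFrame(
            {
                "ohnologon_id": ohno_ann["ohnologon_id"],
                "stratum": np.where(ohno_ann["complex"], "complex", "other"),
            }
        )
        phylo_strata = pd.DataFrame(
            {"ohnologon_id": ohno_ann["ohnologon_id"], "stratum": ohno_ann["phylo_group"]}
        )
        membership = (
            ohno_ann.assign(category=ohno_ann["categories"].str.split(";"))
            .explode("category")
            .query("category != ''")[["category", "ohnologon_id"]]
            .dropna()
        )
        out["stratified_complex"] = retention.stratified_retention(records, complex_strata)
        out["stratified_phylo"] = retention.stratified_retention(records, phylo_strata)
        out["categories"] = retention.category_enrichment(
            records, membership, min_genes=min_category
        )
    return out


def analyze_divergence(
    expression: pd.DataFrame,
    ohnologons: pd.DataFrame,
    ka: Optional[pd.DataFrame] = None,
    seed: Optional[int] = None,
    pair_level: str = "random",
    normalize: str = "none",
    floor=None,
) -> Dict[str, object]:
    """Ohnolog expression-divergence metrics (and optionally Ka), each
    correlated against expression level.

    ``pair_level`` chooses the expression level attached to a pair:
    ``random`` member (default), ``mean`` or ``max`` of the two members.
    """
    levels = _levels_from_matrix(expression, normalize, floor)
    pairs = ohnologons[ohnologons["retained"]].copy()
    split = pairs["members"].str.split(",", expand=True)
    pairs["gene1"], pairs["gene2"] = split[0], split[1]
    pairs = pairs.rename(columns={"ohnologon_id": "pair_id"})[["pair_id", "gene1", "gene2"]]

    l1 = pairs["gene1"].map(levels)
    l2 = pairs["gene2"].map(levels)
    if pair_level == "random":
        rng = np.random.default_rng(seed)
        pick = rng.integers(2, size=len(pairs))
        pair_levels = np.where(pick == 0, l1, l2)
    elif pair_level == "mean":
        pair_levels = (l1 + l2) / 2.0
    elif pair_level == "max":
        pair_levels = np.maximum(l1, l2)
    else:
        raise ValueError(f"unknown pair_level {pair_level!r}")
    pairs["level"] = pair_levels

    matrix = expression
    if "probe_id" in matrix.columns:
        matrix = retention.probe_median(matrix)
    div = metrics.pair_divergence_table(pairs, matrix).merge(
        pairs[["pair_id", "level"]], on="pair_id"
    )
    result: Dict[str, object] = {"divergence": div}
    correlations = {}
    ok = div.dropna(subset=["pearson"])
    # the Pearson metric is a similarity (1 = identical profiles); orient
    # it as a divergence so both metrics share the expected negative sign
    correlations["pearson_divergence"] = metrics.correlate_with_expression(
        1.0 - ok["pearson"], ok["level"]
    )
    correlations["euclidean_divergence"] = metrics.correlate_with_expression(
        div["euclidean"], div["level"]
    )
    if ka is not None:
        ka_merged = ka.merge(pairs[["pair_id", "level"]], on="pair_id")
        correlations["ka"] = metrics.correlate_with_expression(
            ka_merged["ka"], ka_merged["level"]
        )
        result["ka"] = ka_merged
    result["correlations"] = correlations
    return result


def analyze_ko(
    ko: pd.DataFrame,
    expression: pd.DataFrame,
    interval: float = 0.5,
    min_count: int = 30,
    normalize: str = "none",
    floor=None,
    ci: str = "normal",
    seed: Optional[int] = None,
) -> metrics.KOBinResult:
    """Heterozygous-KO minimal fitness binned by expression level."""
    levels = _levels_from_matrix(expression, normalize, floor)
    return metrics.ko_fitness_by_expression(
        ko, levels, interval=interval, min_count=min_count, ci=ci, seed=seed
    )


def headline_fold_experiment(
    n_genes: int = 20_000,
    n_seeds: int = 10,
    master_seed: int = 0,
    k: float = 0.01,
    M: float = 2.0**14,
    log2_mean: float = 8.0,
    log2_sd: float = 2.0,
    Ne: float = 25.0,
    target_retention: float = 0.5,
    interval: float = 1.0,
) -> Dict[str, object]:
    """Cost-model-driven loss simulation scored by the retention pipeline.

    Draws ``n_genes`` expression optima (log2 X0 ~ Normal), computes exact
    halving coefficients, calibrates the loss intensity so genome-wide
    expected retention hits ``target_retention``, then simulates retention
    for ``n_seeds`` independent seeds and runs the extreme-decile
    comparison on each replicate.  Returns the per-seed folds, their
    median, the mean retention, and the binned retention table of the
    first replicate.
    """
    from .model import halving_selection
    from .popgen import PopGenParams, calibrate_loss_intensity, draw_retention

    master = np.random.SeedSequence(master_seed)
    gen_rng = np.random.default_rng(master.spawn(1)[0])
    X0 = np.minimum(2.0 ** gen_rng.normal(log2_mean, log2_sd, n_genes), 0.9 * M)
    s = halving_selection(X0, k, M, "exact")
    intensity = calibrate_loss_intensity(s, Ne, target_retention)
    params = PopGenParams(Ne=Ne, lambda0=1.0, T=intensity)

    folds, retentions = [], []
    first_bins = None
    for child in master.spawn(n_seeds):
        _, retained = draw_retention(s, params, np.random.default_rng(child))
        records = pd.DataFrame(
            {
                "ohnologon_id": [f"o{i:06d}" for i in range(n_genes)],
                "level": np.log2(X0),
                "retained": retained,
            }
        )
        dec = retention.extreme_decile_comparison(records)
        folds.append(dec.fold)
        retentions.append(float(retained.mean()))
        if first_bins is None:
            first_bins = retention.bin_retention(records, interval)
    return {
        "folds": folds,
        "median_fold": float(np.median(folds)),
        "mean_retention": float(np.mean(retentions)),
        "loss_intensity": intensity,
        "bins": first_bins,
        "n_genes": n_genes,
    }


def run_end_to_end(
    config: GeneratorConfig,
    outdir,
    interval: float = 0.2,
    min_bin: int = 30,
    min_category: int = 100,
    ko_interval: float = 0.5,
) -> Dict[str, object]:
    """Generate a dataset, run every analysis, write all outputs and a
    machine-readable summary.  Deterministic given the config seed."""
    from .synth import write_dataset  # local import to keep module load light

    outdir = Path(outdir)
    datadir = outdir / "data"
    seeds = np.random.SeedSequence(config.seed).spawn(3)

    dataset = generate_dataset(config)
    write_dataset(dataset, datadir, config)

    ret = analyze_retention(
        dataset["expression"],
        dataset["ohnologons"],
        annotation=dataset["annotation"],
        interval=interval,
        min_bin=min_bin,
        seed=int(seeds[0].generate_state(1)[0]),
        min_category=min_category,
    )
    div = analyze_divergence(
        dataset["expression"],
        dataset["ohnologons"],
        ka=dataset["ka"],
        seed=int(seeds[1].generate_state(1)[0]),
    )
    ko = analyze_ko(dataset["ko_fitness"], dataset["expression"], interval=ko_interval)

    meta = {"generator": "costex", "seed": config.seed, "config_hash": cio.config_hash(config)}
    cio.write_table(ret["bins"], outdir / "retention_bins.tsv", meta)
    cio.write_table(ret["lowess"], outdir / "retention_lowess.tsv", meta)
    for key in ("stratified_complex", "stratified_phylo", "categories"):
        if key in ret:
            cio.write_table(ret[key], outdir / f"{key}.tsv", meta)
    cio.write_table(div["divergence"], outdir / "divergence.tsv", meta)
    cio.write_table(ko.bins, outdir / "ko_bins.tsv", meta)

    dec = ret["deciles"]
    corr = div["correlations"]
    summary = {
        "seed": config.seed,
        "config_hash": cio.config_hash(config),
        "n_ohnologons": int(len(dataset["ohnologons"])),
        "retention_overall": float(dataset["ohnologons"]["retained"].mean()),
        "decile_freq_bottom": dec.freq_bottom,
        "decile_freq_top": dec.freq_top,
        "decile_fold": dec.fold,
        "decile_p": dec.p,
        "n_bins_included": int(ret["bins"]["included"].sum()),
        "pearson_divergence_r": corr["pearson_divergence"][0],
        "pearson_divergence_p": corr["pearson_divergence"][1],
        "euclidean_divergence_r": corr["euclidean_divergence"][0],
        "euclidean_divergence_p": corr["euclidean_divergence"][1],
        "ka_r": corr["ka"][0],
        "ka_p": corr["ka"][1],
        "ko_r": ko.r,
        "ko_p": ko.p,
    }
    with open(outdir / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("run_end_to_end: wrote bundle to %s", outdir)
    return summary
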