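"""Seeded synthetic-data generator for the whole pipeline.

Produces every input table the analyses need, with the statistical
structure the analyses assume:

* log-normal optimal expression levels (``X0 = 2**z``, z ~ Normal(mu, sd));
* retention after a WGD driven by the cost-model halving coefficient
  through the fixation-scaled loss process (so retention increases with
  expression);
* a retention bonus for protein-complex members, emulated by scaling the
  curvature magnitude (hence the halving coefficient) by a factor;
* per-category loss-rate modifiers (heterogeneity at fixed expression);
* genes x conditions signal matrices whose per-gene log2-of-median
  recovers log2(X0), with ohnolog-pair expression divergence that grows
  as expression falls;
* non-synonymous divergence (Ka) negatively coupled to expression;
* a heterozygous-KO fitness table whose mean fitness loss grows with
  expression.

Everything is drawn from one ``numpy`` generator seeded by the config's
master seed, so output tables are byte-identical across reruns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from . import io as cio
from .model import halving_selection
from .popgen import PopGenParams, calibrate_loss_intensity, draw_retention

__all__ = [
    "CategorySpec",
    "GeneratorConfig",
    "generate_gene_population",
    "generate_expression_matrix",
    "generate_ka_table",
    "generate_ko_fitness_table",
    "generate_dataset",
    "write_dataset",
]


@dataclass(frozen=True)
class CategorySpec:
    """One functional category: membership fraction and a multiplier on
    the neutral loss rate of its members (values < 1 mean over-retained)."""

    name: str
    fraction: float
    loss_rate_modifier: float = 1.0


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic dataset; see module docstring."""

    n_genes: int = 5000
    log2_mean: float = 8.0
    log2_sd: float = 2.0
    n_conditions: int = 58
    profile_sd: float = 1.0          # shared condition-to-condition pattern (log2)
    noise_sd: float = 0.2            # per-cell measurement noise (log2)
    divergence_coupling: float = 0.6  # max extra per-copy profile sd at low expression
    ka_base: float = 0.15
    ka_slope: float = -0.012          # per log2 unit of expression
    ka_noise_sd: float = 0.03
    complex_fraction: float = 0.15
    complex_bonus: float = 3.0        # multiplier on |w''(1)| for complex members
    categories: Tuple[CategorySpec, ...] = (
        CategorySpec("C01", 0.12, 0.7),
        CategorySpec("C02", 0.10, 1.4),
        CategorySpec("C03", 0.08, 1.0),
    )
    phylo_fractions: Tuple[Tuple[str, float], ...] = (
        ("paramecium", 0.55),
        ("ciliate", 0.15),
        ("eukaryote", 0.30),
    )
    ko_noise_sd: float = 0.01
    ko_n_conditions: int = 6
    k: float = 0.01
    M: float = 16384.0
    Ne: float = 25.0
    lambda0: float = 1.0
    T: Optional[float] = None         # None -> calibrate to target_retention
    target_retention: float = 0.5
    selection_off: bool = False       # neutral control: s == 0 for everyone
    seed: int = 0

    _nested = {"categories": CategorySpec}

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if not self.log2_sd >= 0:
            raise ValueError("log2_sd must be >= 0")
        for frac in [self.complex_fraction] + [c.fraction for c in self.categories]:
            if not 0 <= frac <= 1:
                raise ValueError(f"fraction {frac} outside [0, 1]")


def generate_gene_population(
    config: GeneratorConfig, rng: Optional[np.random.Generator] = None
) -> pd.DataFrame:
    """Draw the pre-WGD gene population with expression optima and metadata.

    One row per ohnologon (one ancestral gene).  ``X0`` values exceeding
    the capacity are clipped to ``0.9*M`` with a warning.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_genes
    z = config.log2_mean + config.log2_sd * rng.standard_normal(n)
    X0 = 2.0**z
    if X0.max() >= config.M:
        n_clip = int((X0 >= config.M).sum())
        warnings.warn(
            f"{n_clip} X0 values at or above capacity M={config.M}; "
            "clipping to 0.9*M",
            stacklevel=2,
        )
        X0 = np.minimum(X0, 0.9 * config.M)
    pop = pd.DataFrame(
        {
            "ohnologon_id": [f"o{i:06d}" for i in range(n)],
            "X0": X0,
            "log2_X0": np.log2(X0),
            "complex": rng.random(n) < config.complex_fraction,
        }
    )
    for cat in config.categories:
        pop[f"cat_{cat.name}"] = rng.random(n) < cat.fraction
    groups = [name for name, _ in config.phylo_fractions]
    probs = np.array([f for _, f in config.phylo_fractions], dtype=float)
    probs = probs / probs.sum()
    pop["phylo_group"] = rng.choice(groups, size=n, p=probs)
    return pop


def _selection_and_scale(pop: pd.DataFrame, config: GeneratorConfig):
    """Effective halving coefficients and per-gene loss-rate scale."""
    if config.selection_off:
        s = np.zeros(len(pop))
    else:
        s = halving_selection(pop["X0"].to_numpy(), config.k, config.M, "exact")
        s = np.where(pop["complex"].to_numpy(), s * config.complex_bonus, s)
    scale = np.ones(len(pop))
    for cat in config.categories:
        scale = np.where(pop[f"cat_{cat.name}"].to_numpy(), scale * cat.loss_rate_modifier, scale)
    return s, scale


def simulate_population_retention(
    pop: pd.DataFrame, config: GeneratorConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Attach retention outcomes (and the resolved loss intensity) to the
    population; calibrates ``lambda0*T`` when ``config.T`` is None."""
    s, scale = _selection_and_scale(pop, config)
    if config.T is None:
        intensity = calibrate_loss_intensity(
            s, config.Ne, config.target_retention, lambda_scale=scale
        )
        T = intensity / config.lambda0
    else:
        T = config.T
    params = PopGenParams(Ne=config.Ne, lambda0=config.lambda0, T=T)
    p, retained = draw_retention(s, params, rng, lambda_scale=scale)
    out = pop.copy()
    out["s"] = s
    out["p_retained"] = p
    out["retained"] = retained
    out.attrs["T"] = T
    return out


def _gene_ids(pop: pd.DataFrame) -> pd.DataFrame:
    """Per-ohnologon member gene IDs: two copies when retained, one else."""
    members = [
        f"{oid}a,{oid}b" if ret else f"{oid}a"
        for oid, ret in zip(pop["ohnologon_id"], pop["retained"])
    ]
    return pop.assign(members=members)


def generate_expression_matrix(
    pop: pd.DataFrame, config: GeneratorConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Genes x conditions linear-scale signal table.

    Copies of one ohnologon share a condition pattern; each copy adds
    divergence noise whose sd shrinks linearly with log2 expression (from
    ``divergence_coupling`` at the low end of the configured range to 0 at
    the high end), plus iid measurement noise.
    """
    n_cond = config.n_conditions
    lo = config.log2_mean - 3 * config.log2_sd
    hi = config.log2_mean + 3 * config.log2_sd
    span = max(hi - lo, 1e-12)

    member_lists = pop["members"].str.split(",")
    counts = member_lists.str.len().to_numpy()
    rep = np.repeat(np.arange(len(pop)), counts)  # pop row of each gene copy
    ids = [gid for members in member_lists for gid in members]

    log2_X0 = pop["log2_X0"].to_numpy()
    pattern = config.profile_sd * rng.standard_normal((len(pop), n_cond))
    div_sd = config.divergence_coupling * np.clip((hi - log2_X0) / span, 0.0, 1.0)
    log2_signal = (
        log2_X0[rep, None]
        + pattern[rep]
        + div_sd[rep, None] * rng.standard_normal((len(rep), n_cond))
        + config.noise_sd * rng.standard_normal((len(rep), n_cond))
    )
    mat = pd.DataFrame(
        2.0**log2_signal, columns=[f"cond_{j + 1:02d}" for j in range(n_cond)]
    )
    mat.insert(0, "gene_id", ids)
    return mat


def generate_ka_table(
    pop: pd.DataFrame, config: GeneratorConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Ka for every retained pair: baseline plus a (negative) slope per
    log2 expression unit plus noise, clamped at zero."""
    pairs = pop[pop["retained"]]
    ka = (
        config.ka_base
        + config.ka_slope * (pairs["log2_X0"].to_numpy() - config.log2_mean)
        + config.ka_noise_sd * rng.standard_normal(len(pairs))
    )
    members = pairs["members"].str.split(",", expand=True)
    return pd.DataFrame(
        {
            "pair_id": pairs["ohnologon_id"].to_numpy(),
            "gene1": members[0].to_numpy(),
            "gene2": members[1].to_numpy(),
            "ka": np.maximum(ka, 0.0),
        }
    )


def generate_ko_fitness_table(
    pop: pd.DataFrame, config: GeneratorConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Heterozygous-KO fitness per gene and condition.

    Fitness of the heterozygote is ``1 - s_halving(exact)`` plus
    per-condition noise, so mean fitness loss grows with expression.  One
    row per (gene, condition), using each ohnologon's first copy.
    """
    if config.selection_off:
        s = np.zeros(len(pop))
    else:
        s = halving_selection(pop["X0"].to_numpy(), config.k, config.M, "exact")
    genes = pop["ohnologon_id"].str.cat(["a"] * len(pop))
    n_cond = config.ko_n_conditions
    fitness = (
        1.0
        - np.repeat(s, n_cond)
        + config.ko_noise_sd * rng.standard_normal(len(pop) * n_cond)
    )
    return pd.DataFrame(
        {
            "gene_id": np.repeat(genes.to_numpy(), n_cond),
            "condition": np.tile([f"cond_{j + 1:02d}" for j in range(n_cond)], len(pop)),
            "fitness": fitness,
        }
    )


def _annotation_table(pop: pd.DataFrame, config: GeneratorConfig) -> pd.DataFrame:
    """Per-gene annotation rows; copies inherit the ohnologon metadata."""
    cat_names = [c.name for c in config.categories]
    flags = pop[[f"cat_{n}" for n in cat_names]].to_numpy()
    cats = np.array(
        [";".join(n for n, f in zip(cat_names, row) if f) for row in flags],
        dtype=object,
    )
    member_lists = pop["members"].str.split(",")
    rep = np.repeat(np.arange(len(pop)), member_lists.str.len().to_numpy())
    return pd.DataFrame(
        {
            "gene_id": [g for members in member_lists for g in members],
            "ohnologon_id": pop["ohnologon_id"].to_numpy()[rep],
            "categories": cats[rep],
            "phylo_group": pop["phylo_group"].to_numpy()[rep],
            "complex": pop["complex"].to_numpy()[rep],
        }
    )


def generate_dataset(config: GeneratorConfig) -> Dict[str, pd.DataFrame]:
    """Generate every pipeline input table from the master seed.

    Returns a dict with keys ``genes`` (ground truth incl. s and
    retention probability), ``ohnologons``, ``expression``,
    ``annotation``, ``ka`` and ``ko_fitness``, plus the resolved config
    under the ``"config"`` attrs of ``genes``.
    """
    master = np.random.SeedSequence(config.seed)
    rngs = [np.random.default_rng(s) for s in master.spawn(5)]
    pop = generate_gene_population(config, rngs[0])
    pop = simulate_population_retention(pop, config, rngs[1])
    pop = _gene_ids(pop)
    resolved = replace(config, T=float(pop.attrs["T"]))

    ohnologons = pd.DataFrame(
        {
            "ohnologon_id": pop["ohnologon_id"],
            "wgd_level": "recent",
            "members": pop["members"],
            "retained": pop["retained"],
        }
    )
    dataset = {
        "genes": pop,
        "ohnologons": ohnologons,
        "expression": generate_expression_matrix(pop, config, rngs[2]),
        "annotation": _annotation_table(pop, config),
        "ka": generate_ka_table(pop, config, rngs[3]),
        "ko_fitness": generate_ko_fitness_table(pop, config, rngs[4]),
    }
    dataset["genes"].attrs["config"] = resolved
    return dataset


_FILENAMES = {
    "genes": "gene_models.tsv",
    "ohnologons": "ohnologons.tsv",
    "expression": "expression.tsv",
    "annotation": "annotation.tsv",
    "ka": "ka_pairs.tsv",
    "ko_fitness": "ko_fitness.tsv",
}


def write_dataset(dataset: Dict[str, pd.DataFrame], outdir, config: GeneratorConfig) -> None:
    """Write all tables plus a provenance config snapshot to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    resolved = dataset["genes"].attrs.get("config", config)
    meta = {"generator": "costex", "seed": config.seed, "config_hash": cio.config_hash(resolved)}
    for key, fname in _FILENAMES.items():
        df = dataset[key]
        if key == "genes":
            df = df.drop(columns=["members"], errors="ignore")
        cio.write_table(df, outdir / fname, meta)
    cio.dump_config(resolved, outdir / "generator_config.yaml")
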