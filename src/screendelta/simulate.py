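"""Synthetic screens and omics matrices with known ground truth.

The generators emulate the statistical structure the analysis modules
assume, so every stage has a closed-loop test without external downloads:

* :func:`simulate_screen` — a pooled depletion screen: a Brunello-like
  library (several guides per gene), day-7 baseline plus end-point counts
  in two media conditions with two infection replicates, exponential
  selection with condition-specific per-gene fitness deficits, guide-level
  efficiency jitter, Poisson plating at the configured coverage and
  multinomial read sampling at the configured depth; low-expression
  null-class genes receive TPM < 1 by construction.
* :func:`simulate_metabolome` — lognormal metabolite abundances with
  multiplicative group effects, QC replicates at a configured analytical
  CV, and abundance-dependent (logistic) censoring to exercise imputation.
* :func:`make_ranked_fixture` — a ranked list with a set planted in a
  chosen quantile plus random decoy sets, for the enrichment engine.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, ScreenDeltaWarning
from .io import (
    BASELINE,
    AbundanceMatrix,
    AnnotationSetDB,
    CountMatrix,
    ExpressionTable,
    GuideLibrary,
)
from .enrichment import RankedList


@dataclass
class ScreenSimConfig:
    """Design of a simulated nucleoside-sensitized depletion screen.

    Defaults mirror the screen design the pipeline targets: 4 guides/gene,
    baseline coverage 500 cells/sgRNA, duplicate infections, baseline at
    day 7 and collection at day 28 (21 days of selection). ``effects`` maps
    condition -> {gene -> fitness deficit in doublings/day, <= 0}; genes not
    listed are neutral. ``read_depth`` is the mean reads per guide per
    sample (total reads = depth x number of guides).
    """

    n_genes: int = 2000
    guides_per_gene: int = 4
    n_null_genes: int = 300
    n_control_guides: int = 0
    conditions: tuple[str, ...] = ("minus_uridine", "plus_uridine")
    effects: dict[str, dict[str, float]] = field(default_factory=dict)
    n_replicates: int = 2
    baseline_day: int = 7
    collection_day: int = 28
    coverage_baseline: int = 500
    read_depth: float = 500.0
    growth_rate: float = 1.0
    guide_jitter_sd: float = 0.01
    dispersion: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.guides_per_gene < 1:
            raise ConfigurationError("guides_per_gene must be >= 1")
        if self.coverage_baseline <= 0 or self.read_depth <= 0:
            raise ConfigurationError("coverage and read depth must be > 0")
        if self.n_null_genes < 0 or self.n_null_genes > self.n_genes:
            raise ConfigurationError("0 <= n_null_genes <= n_genes required")
        if len(self.conditions) < 2:
            raise ConfigurationError("need at least two condition labels")
        for cond, genes in self.effects.items():
            if cond not in self.conditions:
                raise ConfigurationError(f"effect condition {cond!r} not declared")
            bad = [g for g, e in genes.items() if e > 0]
            if bad:
                raise ConfigurationError(
                    f"depletion-screen effects must be <= 0; positive for {bad[:3]}"
                )

    def gene_names(self) -> list[str]:
        width = max(4, len(str(self.n_genes)))
        return [f"GENE{i:0{width}d}" for i in range(self.n_genes)]


@dataclass(frozen=True)
class SimTruth:
    """Ground truth of a simulation: per-item class and planted effects."""

    table: pd.DataFrame

    def genes_of_class(self, cls: str) -> pd.Index:
        return self.table.index[self.table["class"] == cls]


def simulate_screen(config: ScreenSimConfig
                    ) -> tuple[GuideLibrary, CountMatrix, ExpressionTable, SimTruth]:
    """Simulate a pooled depletion screen under exponential selection.

    Guide abundance follows n_g(t) = n_g(0) * 2^((r + e_gene,c + delta_g) t)
    with common growth r, condition-specific gene deficit e and guide
    efficiency jitter delta_g ~ Normal(0, sigma_guide^2) shared across
    replicates and conditions. Initial cells per guide are Poisson at the
    baseline coverage, independently per infection replicate. Reads are
    multinomial at the configured depth, so every sample's total is exact.
    """
    rng = np.random.default_rng(config.seed)
    genes = config.gene_names()
    null_genes = genes[config.n_genes - config.n_null_genes:]
    guide_rows = []
    for g in genes:
        for j in range(config.guides_per_gene):
            guide_rows.append((f"{g}_sg{j}", g, False))
    for j in range(config.n_control_guides):
        guide_rows.append((f"CTRL_sg{j}", "control", True))
    lib_frame = pd.DataFrame(
        guide_rows, columns=["guide_id", "gene", "is_control"]
    ).set_index("guide_id")
    library = GuideLibrary(lib_frame)
    n_guides = len(lib_frame)

    effect = {cond: np.zeros(n_guides) for cond in config.conditions}
    gene_idx = {g: i for i, g in enumerate(genes)}
    gene_of_guide = lib_frame["gene"].to_numpy()
    for cond, per_gene in config.effects.items():
        per_guide = np.zeros(n_guides)
        for g, e in per_gene.items():
            if g not in gene_idx:
                raise ConfigurationError(f"effect for unknown gene {g!r}")
            per_guide[gene_of_guide == g] = e
        effect[cond] = per_guide

    jitter = rng.normal(0.0, config.guide_jitter_sd, size=n_guides)
    t0, t1 = config.baseline_day, config.collection_day
    dt = t1 - t0

    counts = {}
    meta_rows = []
    for rep in range(1, config.n_replicates + 1):
        n0 = rng.poisson(config.coverage_baseline, size=n_guides).astype(float)
        base_abund = n0 * 2.0 ** ((config.growth_rate + jitter) * t0)
        counts[f"base_r{rep}"] = _sample_reads(rng, base_abund, config)
        meta_rows.append((f"base_r{rep}", BASELINE, rep, t0))
        for cond in config.conditions:
            abund = base_abund * 2.0 ** (
                (config.growth_rate + effect[cond] + jitter) * dt
            )
            sample = f"{cond}_r{rep}"
            counts[sample] = _sample_reads(rng, abund, config)
            meta_rows.append((sample, cond, rep, t1))

    count_frame = pd.DataFrame(counts, index=lib_frame.index)
    samples = pd.DataFrame(
        meta_rows, columns=["sample_id", "condition", "replicate", "day"]
    ).set_index("sample_id")
    matrix = CountMatrix(count_frame, samples)
    if (count_frame.mean(axis=1) < 1).mean() > 0.5:
        warnings.warn(
            "read depth so low that most guides expect < 1 read",
            ScreenDeltaWarning,
            stacklevel=2,
        )

    tpm = np.empty(config.n_genes)
    is_null = np.isin(genes, null_genes)
    tpm[is_null] = rng.uniform(0.0, 0.99, size=is_null.sum())
    tpm[~is_null] = 2.0 ** rng.uniform(0.1, 8.0, size=(~is_null).sum())
    expression = ExpressionTable(
        pd.Series(tpm, index=pd.Index(genes, name="gene"), name="tpm")
    )

    truth_rows = []
    for g in genes:
        effs = {c: config.effects.get(c, {}).get(g, 0.0) for c in config.conditions}
        if g in set(null_genes):
            cls = "null"
        elif all(e == 0 for e in effs.values()):
            cls = "neutral"
        elif len(set(effs.values())) == 1:
            cls = "core_essential"
        else:
            cls = "conditional_essential"
        truth_rows.append({"item": g, "class": cls,
                           **{f"effect_{c}": e for c, e in effs.items()}})
    truth = SimTruth(pd.DataFrame(truth_rows).set_index("item"))
    return library, matrix, expression, truth


def _sample_reads(rng: np.random.Generator, abundance: np.ndarray,
                  config: ScreenSimConfig) -> np.ndarray:
    """Multinomial read sampling at exact per-sample depth, with an optional
    gamma overdispersion knob applied to relative abundances first."""
    rel = abundance.astype(float)
    if config.dispersion > 0:
        shape = 1.0 / config.dispersion
        rel = rel * rng.gamma(shape, 1.0 / shape, size=len(rel))
    p = rel / rel.sum()
    depth = int(round(config.read_depth * len(rel)))
    return rng.multinomial(depth, p)


def simulate_metabolome(n_features: int = 2000,
                        groups: dict[str, int] | None = None,
                        effect_features: dict[str, float] | None = None,
                        *, qc_group: str = "QC", qc_n: int = 3,
                        cv_qc: float = 0.10,
                        cv_overrides: dict[str, float] | None = None,
                        sample_sd: float = 0.25,
                        missing_model: tuple[float, float] = (8.0, 1.5),
                        seed: int = 0
                        ) -> tuple[AbundanceMatrix, SimTruth]:
    """Simulate a targeted-metabolomics batch.

    Base abundances are lognormal (log2 level ~ Normal(14, 2)); group
    effects multiply by 2^effect; per-sample analytical noise is lognormal
    with ``sample_sd`` on the log2 scale. QC injections scatter around the
    grand mean of each feature at analytical CV ``cv_qc`` (per-feature
    overrides via ``cv_overrides``). Values fall missing by logistic
    censoring P(missing) = 1 / (1 + exp(steepness * (log2 x - threshold)))
    with ``missing_model = (threshold, steepness)``; steepness 0 disables it.
    """
    if groups is None:
        groups = {"control": 4, "knockout": 4}
    if any(n < 2 for n in groups.values()):
        raise ConfigurationError("every group needs >= 2 samples")
    if cv_qc < 0:
        raise ConfigurationError("cv_qc must be >= 0")
    effect_features = effect_features or {}
    rng = np.random.default_rng(seed)
    features = [f"M{i:04d}" for i in range(n_features)]
    base_log2 = rng.normal(14.0, 2.0, size=n_features)
    effects = np.zeros(n_features)
    feat_idx = {f: i for i, f in enumerate(features)}
    for f, e in effect_features.items():
        if f not in feat_idx:
            raise ConfigurationError(f"effect for unknown feature {f!r}")
        effects[feat_idx[f]] = e

    cols = {}
    group_labels = {}
    ref_group = next(iter(groups))
    for g, size in groups.items():
        shift = effects if g != ref_group else np.zeros(n_features)
        for i in range(1, size + 1):
            s = f"{g}_{i}"
            log2x = base_log2 + shift + rng.normal(0.0, sample_sd, n_features)
            cols[s] = 2.0 ** log2x
            group_labels[s] = g
    cvs = np.full(n_features, cv_qc)
    for f, cv in (cv_overrides or {}).items():
        cvs[feat_idx[f]] = cv
    sigma_qc = np.sqrt(np.log1p(cvs**2))  # lognormal sd giving the target CV
    grand = 2.0 ** base_log2
    for i in range(1, qc_n + 1):
        s = f"{qc_group}_{i}"
        cols[s] = grand * np.exp(
            rng.normal(-0.5 * sigma_qc**2, sigma_qc, n_features)
        )
        group_labels[s] = qc_group

    values = pd.DataFrame(cols, index=pd.Index(features, name="feature_id"))
    threshold, steepness = missing_model
    if steepness > 0:
        logit = steepness * (np.log2(values.to_numpy()) - threshold)
        p_missing = 1.0 / (1.0 + np.exp(logit))
        mask = rng.random(values.shape) < p_missing
        arr = values.to_numpy()
        arr[mask] = np.nan
        values = pd.DataFrame(arr, index=values.index, columns=values.columns)
    matrix = AbundanceMatrix(
        values=values,
        groups=pd.Series(group_labels, name="group").rename_axis("sample_id"),
    )
    truth = SimTruth(pd.DataFrame(
        {"class": np.where(effects != 0, "differential", "neutral"),
         "effect_log2": effects,
         "cv_qc": cvs},
        index=pd.Index(features, name="item"),
    ))
    return matrix, truth


def make_ranked_fixture(n_items: int = 1000, planted_set_size: int = 20,
                        planting_quantile: float = 0.05, *,
                        n_decoys: int = 50, decoy_size: int | None = None,
                        seed: int = 0
                        ) -> tuple[RankedList, AnnotationSetDB, SimTruth]:
    """Ranked list of standard-normal stats with a planted set.

    The planted set is drawn from the ``planting_quantile`` fraction of most
    negative stats (quantile 1.0 = uniform, i.e. a true null set); decoy
    sets are uniform random draws of the same size (or ``decoy_size``).
    """
    if planted_set_size >= n_items:
        raise ConfigurationError("planted set must be smaller than the list")
    if not (0 < planting_quantile <= 1):
        raise ConfigurationError("planting_quantile must be in (0, 1]")
    rng = np.random.default_rng(seed)
    stats = rng.normal(0.0, 1.0, n_items)
    items = np.array([f"item{i:05d}" for i in range(n_items)])
    order = np.argsort(stats, kind="mergesort")
    low_pool = items[order[: max(planted_set_size, int(round(planting_quantile * n_items)))]]
    planted = sorted(rng.choice(low_pool, size=planted_set_size, replace=False))
    db = AnnotationSetDB()
    db.add("planted", planted, "set drawn from the most negative stats")
    size = decoy_size or planted_set_size
    for d in range(n_decoys):
        db.add(f"decoy{d:03d}", sorted(rng.choice(items, size=size, replace=False)),
               "uniform random set")
    ranked = RankedList.from_series(pd.Series(stats, index=items))
    cls = pd.Series("background", index=pd.Index(items, name="item"))
    cls.loc[planted] = "planted"
    truth = SimTruth(pd.DataFrame({"class": cls, "stat": pd.Series(stats, index=items)}))
    return ranked, db, truth


def write_screen_sim(out_dir, library: GuideLibrary, matrix: CountMatrix,
                     expression: ExpressionTable, truth: SimTruth) -> None:
    """Write a simulated screen as the pipeline's TSV inputs plus truth.tsv."""
    import pathlib

    from . import io as _io

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _io.write_library(library, out / "library.tsv")
    _io.write_counts(matrix, out / "counts.tsv")
    _io.write_sample_sheet(matrix.samples, out / "samples.tsv")
    _io.write_expression(expression, out / "tpm.tsv")
    truth.table.reset_index().to_csv(out / "truth.tsv", sep="\t", index=False)


def config_from_mapping(mapping: dict) -> ScreenSimConfig:
    """Build a ScreenSimConfig from a plain (e.g. YAML-loaded) mapping."""
    known = {f.name for f in ScreenSimConfig.__dataclass_fields__.values()}
    unknown = set(mapping) - known
    if unknown:
        raise ConfigurationError(f"unknown simulation keys: {sorted(unknown)}")
    if "conditions" in mapping:
        mapping = {**mapping, "conditions": tuple(mapping["conditions"])}
    return ScreenSimConfig(**mapping)
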