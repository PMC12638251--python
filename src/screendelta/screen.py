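"""Conditional-essentiality scoring for a nucleoside-sensitized depletion screen.

The pipeline turns raw sgRNA counts into a differential-essentiality
statistic per gene:

1. normalize each sample to reads per million (RPM);
2. per-guide log2 fold change (LFC) against the mean pre-switch (day-7)
   baseline, with a pseudocount guarding log(0);
3. gene score = mean LFC over the gene's guides, then mean over infection
   replicates, per medium condition;
4. an empirical null from low-expression genes (TPM below a threshold):
   their per-condition score mean and s.d. define z-scores
   Z_c = (score_c - mu_c) / sigma_c;
5. the contrast dZ = Z_minus - Z_plus, ranked ascending so the genes most
   specifically required in the minus condition (e.g. without uridine
   rescue) come first.

The statsmodels-style surface is :class:`ConditionalEssentiality` (model)
and :class:`ConditionalEssentialityResults` (estimates + summary); the
module-level functions are the individual pipeline stages.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, FormatError, ScreenDeltaWarning
from .io import BASELINE, CountMatrix, ExpressionTable, GuideLibrary


@dataclass(frozen=True)
class NullModel:
    """Per-condition empirical null: mean/s.d. of low-expression gene scores.

    ``mu``/``sigma`` are condition-indexed Series in log2 units; ``sigma``
    uses the unbiased (n-1) estimator. ``null_genes`` are the genes that
    defined the distribution.
    """

    mu: pd.Series
    sigma: pd.Series
    n_null: int
    null_genes: pd.Index
    tpm_threshold: float = 1.0

    def __post_init__(self):
        if self.n_null < 2:
            raise ConfigurationError(
                f"empirical null needs >= 2 genes, got {self.n_null}; "
                "supply an explicit null gene list"
            )
        if (self.sigma <= 0).any() or not np.isfinite(self.sigma).all():
            bad = self.sigma.index[~(self.sigma > 0)].tolist()
            raise ConfigurationError(
                f"null s.d. must be positive; degenerate in condition(s) {bad} "
                "(are all null-gene scores identical?)"
            )


def normalize_rpm(counts: CountMatrix | pd.DataFrame) -> pd.DataFrame:
    """Scale each sample to reads per million; zero counts stay zero.

    Raises on an all-zero sample, naming it.
    """
    c = counts.counts if isinstance(counts, CountMatrix) else counts
    totals = c.sum(axis=0)
    zero = totals.index[totals == 0].tolist()
    if zero:
        raise FormatError(f"sample(s) with zero total reads: {zero}")
    return c / totals * 1e6


def drop_dead_guides(counts: CountMatrix) -> CountMatrix:
    """Remove guides with zero reads in every sample (no information)."""
    dead = counts.counts.index[(counts.counts == 0).all(axis=1)]
    if len(dead):
        warnings.warn(
            f"dropping {len(dead)} guides with zero counts in all samples",
            ScreenDeltaWarning,
            stacklevel=2,
        )
        return CountMatrix(counts.counts.drop(index=dead), counts.samples)
    return counts


def guide_lfc(rpm: pd.DataFrame, samples: pd.DataFrame, *,
              pseudocount: float = 1.0,
              baseline_condition: str = BASELINE) -> pd.DataFrame:
    """Per-guide log2 fold change of each post-switch sample vs its baseline.

    LFC(g, s) = log2(rpm(g, s) + pc) - log2(mean_baseline rpm(g, .) + pc).
    The baseline mean is taken over the day-7 sample(s) of the same infection
    replicate when one exists, else pooled over all baseline samples.
    """
    if pseudocount <= 0:
        raise ConfigurationError("pseudocount must be > 0")
    base = samples.index[samples["condition"] == baseline_condition]
    base = [s for s in base if s in rpm.columns]
    if not base:
        raise ConfigurationError(f"no {baseline_condition!r} samples in matrix")
    pooled = rpm[base].mean(axis=1)
    out = {}
    for s in rpm.columns:
        if samples.loc[s, "condition"] == baseline_condition:
            continue
        rep = samples.loc[s, "replicate"]
        matched = [b for b in base if samples.loc[b, "replicate"] == rep]
        ref = rpm[matched].mean(axis=1) if matched else pooled
        out[s] = np.log2(rpm[s] + pseudocount) - np.log2(ref + pseudocount)
    if not out:
        raise ConfigurationError("no non-baseline samples to score")
    return pd.DataFrame(out)


def gene_scores(lfc: pd.DataFrame, library: GuideLibrary,
                samples: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Collapse guide LFCs to per-gene, per-condition scores.

    Two-stage mean: within each (condition, replicate) average the samples,
    take the mean over each gene's guides, then average across replicates.
    Control guides never contribute to gene scores; genes left without a
    usable guide are excluded with a warning. Returns ``(scores, n_guides)``.
    """
    targeting = library.targeting
    usable = lfc.index.intersection(targeting.index)
    if len(usable) == 0:
        raise ConfigurationError("no targeting guides present in the LFC matrix")
    gene_of = targeting.loc[usable, "gene"]
    n_guides = gene_of.groupby(gene_of).size().rename("n_guides")
    dropped = set(targeting["gene"]) - set(n_guides.index)
    if dropped:
        warnings.warn(
            f"{len(dropped)} genes have zero usable guides and are excluded "
            f"(e.g. {sorted(dropped)[:3]})",
            ScreenDeltaWarning,
            stacklevel=2,
        )
    meta = samples.loc[list(lfc.columns)]
    conditions = [c for c in dict.fromkeys(meta["condition"]) if c != BASELINE]
    per_cond = {}
    for cond in conditions:
        cond_samples = meta.index[meta["condition"] == cond]
        rep_scores = []
        for rep in sorted(meta.loc[cond_samples, "replicate"].unique()):
            cols = [s for s in cond_samples if meta.loc[s, "replicate"] == rep]
            guide_vec = lfc.loc[usable, cols].mean(axis=1)
            rep_scores.append(guide_vec.groupby(gene_of).mean())
        per_cond[cond] = pd.concat(rep_scores, axis=1).mean(axis=1)
    scores = pd.DataFrame(per_cond)
    scores.index.name = "gene"
    return scores.sort_index(), n_guides.sort_index()


def fit_null(scores: pd.DataFrame, expression: ExpressionTable,
             tpm_threshold: float = 1.0) -> NullModel:
    """Empirical null from genes expressed below ``tpm_threshold`` TPM.

    Genes absent from the expression table are treated as expressed (never
    allowed to contaminate the null) with a warning.
    """
    tpm = expression.tpm
    unknown = scores.index.difference(tpm.index)
    if len(unknown):
        warnings.warn(
            f"{len(unknown)} scored genes missing from the expression table "
            "are treated as expressed",
            ScreenDeltaWarning,
            stacklevel=2,
        )
    known = scores.index.intersection(tpm.index)
    null_genes = known[tpm.loc[known] < tpm_threshold]
    if len(null_genes) < 2:
        raise ConfigurationError(
            f"only {len(null_genes)} genes below TPM {tpm_threshold}; "
            "supply an explicit null gene list"
        )
    sub = scores.loc[null_genes]
    return NullModel(
        mu=sub.mean(axis=0),
        sigma=sub.std(axis=0, ddof=1),
        n_null=len(null_genes),
        null_genes=null_genes,
        tpm_threshold=tpm_threshold,
    )


def compute_z(scores: pd.DataFrame, null: NullModel) -> pd.DataFrame:
    """Z_c = (score_c - mu_c) / sigma_c, per condition."""
    return (scores - null.mu) / null.sigma


def delta_z(z: pd.DataFrame, minus_condition: str, plus_condition: str) -> pd.Series:
    """dZ = Z_minus - Z_plus; most negative = most specifically required
    without rescue."""
    for lab in (minus_condition, plus_condition):
        if lab not in z.columns:
            raise ConfigurationError(
                f"condition {lab!r} not among scored conditions {list(z.columns)}"
            )
    return (z[minus_condition] - z[plus_condition]).rename("delta_z")


class ConditionalEssentiality:
    """Model: differential gene essentiality between two media conditions.

    Parameters
    ----------
    counts : CountMatrix
        sgRNA read counts with baseline (pre-switch) and end-point samples.
    library : GuideLibrary
        sgRNA -> gene map; control guides are kept in RPM totals but never
        scored.
    expression : ExpressionTable
        TPM table nominating low-expression genes for the empirical null.
    minus, plus : str
        Condition labels contrasted as dZ = Z_minus - Z_plus.
    pseudocount : float
        Added to RPM inside both log2 terms (default 1).
    tpm_threshold : float
        Genes below this TPM define the null (default 1).
    """

    def __init__(self, counts: CountMatrix, library: GuideLibrary,
                 expression: ExpressionTable, *,
                 minus: str = "minus_uridine", plus: str = "plus_uridine",
                 pseudocount: float = 1.0, tpm_threshold: float = 1.0):
        self.counts = counts
        self.library = library
        self.expression = expression
        self.minus = minus
        self.plus = plus
        self.pseudocount = float(pseudocount)
        self.tpm_threshold = float(tpm_threshold)

    def fit(self) -> "ConditionalEssentialityResults":
        counts = drop_dead_guides(self.counts)
        rpm = normalize_rpm(counts)
        lfc = guide_lfc(rpm, counts.samples, pseudocount=self.pseudocount)
        scores, n_guides = gene_scores(lfc, self.library, counts.samples)
        null = fit_null(scores, self.expression, self.tpm_threshold)
        z = compute_z(scores, null)
        dz = delta_z(z, self.minus, self.plus)
        table = pd.DataFrame(
            {
                "n_guides": n_guides.loc[scores.index],
                "score_minus": scores[self.minus],
                "score_plus": scores[self.plus],
                "Z_minus": z[self.minus],
                "Z_plus": z[self.plus],
                "delta_z": dz,
                "is_null_gene": scores.index.isin(null.null_genes),
            }
        )
        # deterministic: ascending dZ, ties broken lexicographically by gene
        table = table.sort_index(kind="mergesort").sort_values(
            "delta_z", kind="mergesort"
        )
        return ConditionalEssentialityResults(self, table, null, scores, z)


class ConditionalEssentialityResults:
    """Fitted screen scores: per-gene LFC scores, z-scores and dZ.

    ``table`` holds all genes (null genes flagged, still scored);
    :meth:`ranked` excludes null genes, matching the convention that the
    genes defining the null are withheld from downstream ranked analyses.
    """

    def __init__(self, model: ConditionalEssentiality, table: pd.DataFrame,
                 null: NullModel, scores: pd.DataFrame, z: pd.DataFrame):
        self.model = model
        self.table = table
        self.null = null
        self.scores = scores
        self.z = z

    def ranked(self) -> pd.DataFrame:
        """Ascending-dZ table of expressed genes only."""
        return self.table[~self.table["is_null_gene"]]

    def ranked_series(self) -> pd.Series:
        """dZ of expressed genes, ascending — ready for preranked enrichment."""
        return self.ranked()["delta_z"]

    def to_tsv(self, path) -> None:
        out = self.table.reset_index().rename(columns={"index": "gene"})
        out["is_null_gene"] = out["is_null_gene"].map({True: "true", False: "false"})
        out.to_csv(path, sep="\t", index=False)

    def summary(self, top: int = 10) -> str:
        m = self.model
        lines = [
            "Conditional essentiality (z-score screen scoring)",
            "=" * 58,
            f"genes scored: {len(self.table)}   "
            f"null genes (TPM < {m.tpm_threshold:g}): {self.null.n_null}",
            f"contrast: dZ = Z[{m.minus}] - Z[{m.plus}]   pseudocount: {m.pseudocount:g}",
            "",
            "empirical null (low-expression genes):",
        ]
        for cond in self.scores.columns:
            lines.append(
                f"  {cond:>16s}: mu = {self.null.mu[cond]: .4f}   "
                f"sigma = {self.null.sigma[cond]:.4f}"
            )
        lines += ["", f"top {top} differentially required genes (ascending dZ):",
                  f"{'gene':<14s}{'n_guides':>9s}{'Z_minus':>10s}{'Z_plus':>10s}{'delta_z':>10s}"]
        for gene, row in self.ranked().head(top).iterrows():
            lines.append(
                f"{str(gene):<14s}{int(row.n_guides):>9d}{row.Z_minus:>10.3f}"
                f"{row.Z_plus:>10.3f}{row.delta_z:>10.3f}"
            )
        return "\n".join(lines)

    def plot_z(self, ax=None):
        """Scatter of per-gene z-scores, plus-condition on x, minus on y."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 5))
        expressed = self.ranked()
        ax.scatter(expressed["Z_plus"], expressed["Z_minus"], s=6, alpha=0.5,
                   c="#33557f", linewidths=0)
        lim = float(np.nanmax(np.abs(expressed[["Z_plus", "Z_minus"]].to_numpy()))) * 1.05
        ax.plot([-lim, lim], [-lim, lim], ls="--", lw=0.8, c="grey")
        ax.set_xlabel(f"Z ({self.model.plus})")
        ax.set_ylabel(f"Z ({self.model.minus})")
        ax.set_title("gene representation by condition")
        return ax
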