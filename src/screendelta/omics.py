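"""Targeted-omics statistics: QC filtering, normalization, differential
abundance, detection filtering, downshifted-normal imputation, contaminant
filtering and isotopologue summarization.

These are the per-feature statistics applied downstream of vendor peak
integration: a metabolomics branch (QC CV filter -> differential abundance
with BH correction) and a proteomics branch (detection filter -> downshifted
normal imputation -> t-tests; for affinity-purification data additionally
bait-replicate and contaminant-score filters).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import ConfigurationError
from .io import AbundanceMatrix


# ---------------------------------------------------------------------------
# QC / normalization / detection
# ---------------------------------------------------------------------------

def cv_qc_filter(matrix: AbundanceMatrix, qc_group: str,
                 max_cv: float = 0.30) -> tuple[AbundanceMatrix, pd.DataFrame]:
    """Discard features whose coefficient of variation across QC injections
    exceeds ``max_cv``.

    CV = unbiased sample s.d. / mean over present raw QC intensities.
    Features with fewer than two present QC values are removed with the
    distinct reason "insufficient QC coverage". Returns the filtered matrix
    and a removal report (feature, cv, reason).
    """
    if max_cv <= 0:
        raise ConfigurationError("max_cv must be > 0")
    qc_samples = matrix.samples_in(qc_group)
    if len(qc_samples) < 2:
        raise ConfigurationError(
            f"need >= 2 samples in QC group {qc_group!r}, found {len(qc_samples)}"
        )
    qc = matrix.values[qc_samples]
    n_present = qc.notna().sum(axis=1)
    cv = qc.std(axis=1, ddof=1) / qc.mean(axis=1)
    removed = []
    keep = []
    for feat in matrix.values.index:
        if n_present[feat] < 2:
            removed.append((feat, np.nan, "insufficient QC coverage"))
        elif cv[feat] > max_cv:
            removed.append((feat, float(cv[feat]), f"CV > {max_cv:g}"))
        else:
            keep.append(feat)
    report = pd.DataFrame(removed, columns=["feature", "cv", "reason"])
    iso = (matrix.isotopologue.loc[keep]
           if matrix.isotopologue is not None else None)
    filtered = AbundanceMatrix(
        values=matrix.values.loc[keep], groups=matrix.groups,
        log_scale=matrix.log_scale, isotopologue=iso,
    )
    return filtered, report


def internal_standard_normalize(matrix: AbundanceMatrix,
                                standard_feature: str) -> AbundanceMatrix:
    """Divide every intensity by its sample's internal-standard intensity.

    The standard row becomes all-ones; re-normalizing is therefore the
    identity. Errors (naming the samples) if the standard is missing
    anywhere.
    """
    if standard_feature not in matrix.values.index:
        raise ConfigurationError(f"standard {standard_feature!r} not in matrix")
    std = matrix.values.loc[standard_feature]
    absent = std.index[std.isna()].tolist()
    if absent:
        raise ConfigurationError(
            f"internal standard {standard_feature!r} missing in sample(s) {absent}"
        )
    return AbundanceMatrix(
        values=matrix.values / std, groups=matrix.groups,
        log_scale=matrix.log_scale, isotopologue=matrix.isotopologue,
    )


def detection_filter(matrix: AbundanceMatrix, min_present: int,
                     groups: list[str] | None = None) -> AbundanceMatrix:
    """Keep a feature iff at least one group has >= ``min_present`` present
    values (the "quantified in at least N samples of one group" rule)."""
    if min_present < 1:
        raise ConfigurationError("min_present must be >= 1")
    labels = groups if groups is not None else sorted(set(matrix.groups))
    keep_mask = pd.Series(False, index=matrix.values.index)
    for g in labels:
        cols = matrix.samples_in(g)
        if cols:
            keep_mask |= matrix.values[cols].notna().sum(axis=1) >= min_present
    keep = matrix.values.index[keep_mask]
    iso = (matrix.isotopologue.loc[keep]
           if matrix.isotopologue is not None else None)
    return AbundanceMatrix(
        values=matrix.values.loc[keep], groups=matrix.groups,
        log_scale=matrix.log_scale, isotopologue=iso,
    )


# ---------------------------------------------------------------------------
# imputation
# ---------------------------------------------------------------------------

def impute_downshifted_normal(matrix: AbundanceMatrix, *, width: float = 0.3,
                              shift: float = 1.8, seed: int | None = None,
                              per_sample: bool = True
                              ) -> tuple[AbundanceMatrix, pd.DataFrame]:
    """Fill missing log-scale values from a downshifted normal distribution.

    Each missing cell in sample s is drawn from
    Normal(mean_s - shift * sd_s, (width * sd_s)^2) where mean_s/sd_s are the
    present-value statistics of that sample (or of the whole matrix with
    ``per_sample=False``) — emulating left-censored label-free proteomics
    intensities. Present values are untouched. Returns the imputed matrix
    and a log of imputed cell coordinates (feature, sample, value).
    """
    if not matrix.log_scale:
        raise ConfigurationError("imputation expects a log-scale matrix")
    if width < 0:
        raise ConfigurationError("width must be >= 0")
    rng = np.random.default_rng(seed)
    values = matrix.values.copy()
    arr = values.to_numpy(dtype=float)
    if per_sample:
        for j, s in enumerate(values.columns):
            col = arr[:, j]
            present = col[~np.isnan(col)]
            if len(present) < 2:
                raise ConfigurationError(
                    f"sample {s!r} has {len(present)} present values; "
                    "s.d. undefined"
                )
        means = np.nanmean(arr, axis=0)
        sds = np.nanstd(arr, axis=0, ddof=1)
    else:
        flat = arr[~np.isnan(arr)]
        if len(flat) < 2:
            raise ConfigurationError("matrix has < 2 present values")
        means = np.full(arr.shape[1], flat.mean())
        sds = np.full(arr.shape[1], flat.std(ddof=1))
    log_rows = []
    for j, s in enumerate(values.columns):
        miss = np.isnan(arr[:, j])
        n = int(miss.sum())
        if n == 0:
            continue
        draws = rng.normal(means[j] - shift * sds[j], width * sds[j], size=n)
        arr[miss, j] = draws
        for feat, val in zip(values.index[miss], draws):
            log_rows.append((feat, s, float(val)))
    imputed = pd.DataFrame(arr, index=values.index, columns=values.columns)
    out = AbundanceMatrix(values=imputed, groups=matrix.groups, log_scale=True,
                          isotopologue=matrix.isotopologue)
    return out, pd.DataFrame(log_rows, columns=["feature", "sample", "value"])


# ---------------------------------------------------------------------------
# differential abundance
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DifferentialOptions:
    log_transform: bool = True
    equal_var: bool = True  # Student's t; False -> Welch


def differential(matrix: AbundanceMatrix, group_a: str, group_b: str, *,
                 log_transform: bool = True,
                 equal_var: bool = True) -> pd.DataFrame:
    """Two-sided two-sample t-test per feature with BH FDR across features.

    log2fc is mean(log2 B) - mean(log2 A) when ``log_transform`` (or when the
    matrix is already log scale), else log2(mean B / mean A). Features with
    fewer than two present values in either group are reported untested;
    zero pooled variance yields a missing p flagged "degenerate variance"
    rather than a fabricated 0 or 1. Missing values are handled
    pairwise-complete — no imputation happens here.
    """
    for g in (group_a, group_b):
        if not matrix.samples_in(g):
            raise ConfigurationError(f"group {g!r} has no samples")
    a_cols = matrix.samples_in(group_a)
    b_cols = matrix.samples_in(group_b)
    already_log = matrix.log_scale
    rows = []
    for feat in matrix.values.index:
        a = matrix.values.loc[feat, a_cols].dropna().to_numpy(dtype=float)
        b = matrix.values.loc[feat, b_cols].dropna().to_numpy(dtype=float)
        row = {"feature": feat, "n_A": len(a), "n_B": len(b),
               "log2fc": np.nan, "t_stat": np.nan, "p_value": np.nan,
               "tested": False, "flag": ""}
        if len(a) < 2 or len(b) < 2:
            row["flag"] = "insufficient observations"
            rows.append(row)
            continue
        if already_log:
            la, lb = a, b
            row["log2fc"] = lb.mean() - la.mean()
        elif log_transform:
            la, lb = np.log2(a), np.log2(b)
            row["log2fc"] = lb.mean() - la.mean()
        else:
            la, lb = a, b
            row["log2fc"] = np.log2(b.mean() / a.mean())
        if np.var(la) == 0 and np.var(lb) == 0 and la.mean() == lb.mean():
            # identical constant groups: no evidence of difference
            row.update(t_stat=0.0, p_value=1.0, tested=True)
            rows.append(row)
            continue
        if np.var(la, ddof=1) == 0 and np.var(lb, ddof=1) == 0:
            row["flag"] = "degenerate variance"
            rows.append(row)
            continue
        t, p = stats.ttest_ind(lb, la, equal_var=equal_var)
        row.update(t_stat=float(t), p_value=float(p), tested=True)
        rows.append(row)
    table = pd.DataFrame(rows).set_index("feature")
    table["q_value"] = np.nan
    tested = table.index[table["tested"] & table["p_value"].notna()]
    if len(tested):
        table.loc[tested, "q_value"] = multipletests(
            table.loc[tested, "p_value"], method="fdr_bh"
        )[1]
    return table[["log2fc", "t_stat", "p_value", "q_value", "n_A", "n_B",
                  "tested", "flag"]]


class DifferentialAbundance:
    """Model: per-feature differential abundance between two groups."""

    def __init__(self, matrix: AbundanceMatrix, group_a: str, group_b: str, *,
                 log_transform: bool = True, equal_var: bool = True):
        self.matrix = matrix
        self.group_a = group_a
        self.group_b = group_b
        self.options = DifferentialOptions(log_transform, equal_var)

    def fit(self) -> "DifferentialAbundanceResults":
        table = differential(
            self.matrix, self.group_a, self.group_b,
            log_transform=self.options.log_transform,
            equal_var=self.options.equal_var,
        )
        return DifferentialAbundanceResults(self, table)


class DifferentialAbundanceResults:
    def __init__(self, model: DifferentialAbundance, table: pd.DataFrame):
        self.model = model
        self.table = table

    def ranked_series(self) -> pd.Series:
        """log2 fold changes of tested features, for preranked enrichment."""
        t = self.table[self.table["tested"]]
        return t["log2fc"]

    def significant(self, q: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["q_value"] < q]

    def to_tsv(self, path) -> None:
        self.table.reset_index().to_csv(path, sep="\t", index=False)

    def summary(self, top: int = 10) -> str:
        m = self.model
        tested = self.table["tested"].sum()
        lines = [
            "Differential abundance (two-sided t-test, BH FDR)",
            "=" * 58,
            f"contrast: {m.group_b} vs {m.group_a}   "
            f"{'Student' if m.options.equal_var else 'Welch'} t, "
            f"{'log2' if m.options.log_transform else 'raw'} scale",
            f"features: {len(self.table)} total, {tested} tested, "
            f"{len(self.significant())} at q < 0.05",
            "",
            f"{'feature':<22s}{'log2fc':>9s}{'t':>9s}{'p':>11s}{'q':>11s}",
        ]
        shown = self.table[self.table["tested"]].sort_values("p_value").head(top)
        for feat, r in shown.iterrows():
            lines.append(
                f"{str(feat)[:21]:<22s}{r.log2fc:>9.3f}{r.t_stat:>9.3f}"
                f"{r.p_value:>11.3e}{r.q_value:>11.3e}"
            )
        return "\n".join(lines)

    def plot_volcano(self, ax=None, q: float = 0.05):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4))
        t = self.table[self.table["tested"]]
        sig = t["q_value"] < q
        ax.scatter(t.loc[~sig, "log2fc"], -np.log10(t.loc[~sig, "p_value"]),
                   s=8, c="grey", alpha=0.6, linewidths=0)
        ax.scatter(t.loc[sig, "log2fc"], -np.log10(t.loc[sig, "p_value"]),
                   s=10, c="#b03030", alpha=0.8, linewidths=0)
        ax.set_xlabel(f"log2 FC ({self.model.group_b} / {self.model.group_a})")
        ax.set_ylabel("-log10 p")
        return ax


# ---------------------------------------------------------------------------
# contaminant filtering and isotopologues
# ---------------------------------------------------------------------------

def crapome_filter(candidates, replicate_detection: pd.Series,
                   crapome_scores: pd.Series | None = None,
                   max_score: float = 2.5) -> list[str]:
    """Affinity-purification contaminant filter.

    Keep a feature iff it was detected in every bait replicate AND its
    average spectral score in the contaminant repository is <= ``max_score``
    (strict exclusion above the threshold). Features without a score count
    as score 0.
    """
    if isinstance(candidates, pd.DataFrame):
        features = list(candidates.index)
    else:
        features = list(candidates)
    scores = crapome_scores if crapome_scores is not None else pd.Series(dtype=float)
    kept = []
    for f in features:
        detected = bool(replicate_detection.get(f, False))
        score = float(scores.get(f, 0.0))
        if detected and score <= max_score:
            kept.append(f)
    return kept


@dataclass(frozen=True)
class IsotopologueSummary:
    """Per (metabolite, m+k) labelled fractions and per-metabolite totals.

    ``fractions`` is indexed by (metabolite, k) with one column per sample;
    within each metabolite and sample the fractions sum to 1 (or are all NaN
    when nothing was detected). ``total_abundance`` is metabolite x sample.
    """

    fractions: pd.DataFrame
    total_abundance: pd.DataFrame


def isotopologue_fractions(matrix: AbundanceMatrix) -> IsotopologueSummary:
    """Normalize isotopologue abundances to fractional enrichment.

    fraction_k = abundance_{m+k} / sum_j abundance_{m+j} per metabolite and
    sample; missing isotopologue measurements count as 0 abundance, and an
    all-zero vector yields NaN fractions (undefined, reported missing).
    """
    if matrix.isotopologue is None:
        raise ConfigurationError("matrix carries no isotopologue index")
    iso = matrix.isotopologue
    vals = matrix.values.fillna(0.0)
    if (vals.to_numpy() < 0).any():
        raise ConfigurationError("isotopologue abundances must be >= 0")
    key = pd.MultiIndex.from_arrays(
        [iso["metabolite"], iso["k"]], names=["metabolite", "k"]
    )
    stacked = vals.set_axis(key, axis=0).sort_index()
    totals = stacked.groupby(level="metabolite").sum()
    denom = totals.reindex(stacked.index.get_level_values("metabolite")).to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = stacked.to_numpy() / denom
    fractions = pd.DataFrame(frac, index=stacked.index, columns=stacked.columns)
    return IsotopologueSummary(fractions=fractions, total_abundance=totals)
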