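"""Screen scoring: RPM, guide LFC, gene scores, empirical null, Z and dZ."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import screendelta as sd
from screendelta.io import BASELINE
from screendelta.screen import (
    compute_z,
    delta_z,
    fit_null,
    gene_scores,
    guide_lfc,
    normalize_rpm,
)


class TestNormalizeRpm:
    def test_scales_to_reads_per_million(self):
        df = pd.DataFrame({"s": [10, 30, 60]}, index=["g1", "g2", "g3"])
        out = normalize_rpm(df)
        assert list(out["s"]) == [100000.0, 300000.0, 600000.0]

    def test_single_guide_gets_full_million(self):
        df = pd.DataFrame({"s": [7]}, index=["g1"])
        assert normalize_rpm(df).loc["g1", "s"] == 1e6

    def test_all_zero_sample_names_sample(self):
        df = pd.DataFrame({"ok": [1, 2], "dead": [0, 0]}, index=["g1", "g2"])
        with pytest.raises(sd.FormatError, match="dead"):
            normalize_rpm(df)

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_columns_sum_to_one_million(self, seed):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(rng.integers(0, 1000, size=(50, 4)) + 1)
        sums = normalize_rpm(df).to_numpy().sum(axis=0)
        # independent summation of the output columns
        assert np.allclose(sums, 1e6, rtol=1e-9)


class TestGuideLfc:
    @pytest.fixture
    def samples(self):
        return pd.DataFrame(
            {"condition": [BASELINE, "minus_uridine"], "replicate": [1, 1],
             "day": [7, 28]},
            index=pd.Index(["b1", "m1"], name="sample_id"),
        )

    def test_equal_rpm_gives_zero(self, samples):
        rpm = pd.DataFrame({"b1": [100.0], "m1": [100.0]}, index=["g"])
        assert guide_lfc(rpm, samples).loc["g", "m1"] == 0.0

    def test_depletion_formula(self, samples):
        rpm = pd.DataFrame({"b1": [100.0], "m1": [25.0]}, index=["g"])
        got = guide_lfc(rpm, samples, pseudocount=1.0).loc["g", "m1"]
        assert got == pytest.approx(math.log2(26 / 101), abs=1e-12)

    def test_pseudocount_guards_double_zero(self, samples):
        rpm = pd.DataFrame({"b1": [0.0], "m1": [0.0]}, index=["g"])
        assert guide_lfc(rpm, samples).loc["g", "m1"] == 0.0

    def test_replicate_matched_baseline_preferred(self):
        samples = pd.DataFrame(
            {"condition": [BASELINE, BASELINE, "minus_uridine"],
             "replicate": [1, 2, 2], "day": [7, 7, 28]},
            index=pd.Index(["b1", "b2", "m2"], name="sample_id"),
        )
        rpm = pd.DataFrame({"b1": [100.0], "b2": [400.0], "m2": [400.0]},
                           index=["g"])
        # replicate-2 endpoint compares against the replicate-2 baseline only
        assert guide_lfc(rpm, samples).loc["g", "m2"] == 0.0

    def test_pooled_baseline_when_replicate_unmatched(self):
        samples = pd.DataFrame(
            {"condition": [BASELINE, BASELINE, "minus_uridine"],
             "replicate": [1, 2, 3], "day": [7, 7, 28]},
            index=pd.Index(["b1", "b2", "m3"], name="sample_id"),
        )
        rpm = pd.DataFrame({"b1": [100.0], "b2": [400.0], "m3": [250.0]},
                           index=["g"])
        assert guide_lfc(rpm, samples).loc["g", "m3"] == 0.0

    def test_zero_pseudocount_rejected(self, samples):
        rpm = pd.DataFrame({"b1": [1.0], "m1": [1.0]}, index=["g"])
        with pytest.raises(sd.ConfigurationError):
            guide_lfc(rpm, samples, pseudocount=0.0)


class TestGeneScores:
    def test_mean_over_guides(self, tiny_samples):
        lib = sd.GuideLibrary(pd.DataFrame(
            {"gene": ["A"] * 4, "is_control": [False] * 4},
            index=pd.Index([f"A_sg{i}" for i in range(4)], name="guide_id"),
        ))
        lfc = pd.DataFrame({"minus_r1": [-2.0, -1.0, -3.0, -2.0]},
                           index=lib.guides)
        scores, n_guides = gene_scores(lfc, lib, tiny_samples)
        assert scores.loc["A", "minus_uridine"] == -2.0
        assert n_guides["A"] == 4

    def test_mean_over_replicates(self, tiny_samples):
        lib = sd.GuideLibrary(pd.DataFrame(
            {"gene": ["A"], "is_control": [False]},
            index=pd.Index(["A_sg0"], name="guide_id"),
        ))
        lfc = pd.DataFrame({"minus_r1": [-2.0], "minus_r2": [-3.0]},
                           index=lib.guides)
        scores, _ = gene_scores(lfc, lib, tiny_samples)
        assert scores.loc["A", "minus_uridine"] == -2.5

    def test_control_guides_never_scored(self, tiny_library, tiny_samples):
        lfc = pd.DataFrame({"minus_r1": [1.0] * 5}, index=tiny_library.guides)
        scores, _ = gene_scores(lfc, tiny_library, tiny_samples)
        assert "control" not in scores.index

    def test_matches_two_stage_mean_oracle(self, tiny_samples):
        rng = np.random.default_rng(1)
        genes = [f"G{i}" for i in range(10)]
        guide_rows = [(f"{g}_sg{j}", g) for g in genes for j in range(3)]
        lib = sd.GuideLibrary(pd.DataFrame(
            {"gene": [g for _, g in guide_rows],
             "is_control": [False] * len(guide_rows)},
            index=pd.Index([gid for gid, _ in guide_rows], name="guide_id"),
        ))
        cols = ["minus_r1", "minus_r2", "plus_r1", "plus_r2"]
        lfc = pd.DataFrame(rng.normal(size=(len(lib), 4)), index=lib.guides,
                           columns=cols)
        scores, _ = gene_scores(lfc, lib, tiny_samples)
        # independent nested-loop two-stage mean
        for g in genes:
            guides = [f"{g}_sg{j}" for j in range(3)]
            for cond, reps in [("minus_uridine", ["minus_r1", "minus_r2"]),
                               ("plus_uridine", ["plus_r1", "plus_r2"])]:
                rep_means = []
                for r in reps:
                    rep_means.append(
                        sum(lfc.loc[gid, r] for gid in guides) / len(guides)
                    )
                expected = sum(rep_means) / len(rep_means)
                assert scores.loc[g, cond] == pytest.approx(expected, abs=1e-12)


class TestNullModel:
    def _scores(self, vals):
        return pd.DataFrame({"minus_uridine": vals},
                            index=pd.Index([f"G{i}" for i in range(len(vals))],
                                           name="gene"))

    def _expr(self, genes, tpm=0.5):
        return sd.ExpressionTable(pd.Series(tpm, index=pd.Index(genes, name="gene")))

    def test_mean_and_unbiased_sd(self):
        scores = self._scores([-1.0, 0.0, 1.0])
        null = fit_null(scores, self._expr(scores.index))
        assert null.mu["minus_uridine"] == 0.0
        assert null.sigma["minus_uridine"] == 1.0

    def test_constant_null_scores_rejected(self):
        scores = self._scores([0.3, 0.3, 0.3])
        with pytest.raises(sd.ConfigurationError, match="s.d."):
            fit_null(scores, self._expr(scores.index))

    def test_too_few_null_genes_instructs_user(self):
        scores = self._scores([-1.0, 0.0, 1.0])
        expr = sd.ExpressionTable(pd.Series(
            {"G0": 0.5, "G1": 10.0, "G2": 10.0}).rename_axis("gene"))
        with pytest.raises(sd.ConfigurationError, match="null gene list"):
            fit_null(scores, expr)

    def test_unknown_genes_treated_as_expressed_with_warning(self):
        scores = self._scores([-1.0, 0.0, 1.0, 5.0])
        expr = sd.ExpressionTable(pd.Series(
            {"G0": 0.5, "G1": 0.5, "G2": 0.5}).rename_axis("gene"))
        with pytest.warns(sd.ScreenDeltaWarning, match="treated as expressed"):
            null = fit_null(scores, expr)
        assert "G3" not in null.null_genes

    def test_recovers_simulated_null_parameters(self):
        rng = np.random.default_rng(0)
        n = 500
        scores = self._scores(rng.normal(0.2, 0.5, size=n))
        null = fit_null(scores, self._expr(scores.index))
        # sampling-error bound: 3 sigma / sqrt(n) ~ 0.067
        assert abs(null.mu["minus_uridine"] - 0.2) < 0.07
        assert abs(null.sigma["minus_uridine"] - 0.5) < 0.07


class TestZAndDelta:
    def test_z_formula(self):
        scores = pd.DataFrame({"c": [-2.0, 0.0]}, index=["A", "B"])
        null = sd.NullModel(mu=pd.Series({"c": 0.0}),
                            sigma=pd.Series({"c": 1.0}), n_null=2,
                            null_genes=pd.Index([]))
        z = compute_z(scores, null)
        assert z.loc["A", "c"] == -2.0
        assert z.loc["B", "c"] == 0.0

    def test_affine_invariance_of_z(self):
        rng = np.random.default_rng(3)
        scores = pd.DataFrame(
            {"c": rng.normal(size=30)},
            index=pd.Index([f"G{i}" for i in range(30)], name="gene"),
        )
        expr = sd.ExpressionTable(
            pd.Series(0.5, index=scores.index))
        z1 = compute_z(scores, fit_null(scores, expr))
        z2 = compute_z(scores * 3.0 + 7.0, fit_null(scores * 3.0 + 7.0, expr))
        pd.testing.assert_frame_equal(z1, z2)

    def test_delta_z_values(self):
        z = pd.DataFrame({"minus": [-6.0, 1.0], "plus": [-1.0, 1.0]},
                         index=["A", "B"])
        dz = delta_z(z, "minus", "plus")
        assert dz["A"] == -5.0
        assert dz["B"] == 0.0

    def test_unknown_condition_label(self):
        z = pd.DataFrame({"minus": [0.0]}, index=["A"])
        with pytest.raises(sd.ConfigurationError, match="not among"):
            delta_z(z, "minus", "typo")

    def test_condition_swap_negates_and_reverses(self):
        rng = np.random.default_rng(4)
        z = pd.DataFrame({"minus": rng.normal(size=40),
                          "plus": rng.normal(size=40)},
                         index=[f"G{i:02d}" for i in range(40)])
        fwd = delta_z(z, "minus", "plus")
        rev = delta_z(z, "plus", "minus")
        assert np.allclose(fwd, -rev)
        order_fwd = fwd.sort_values(kind="mergesort").index
        order_rev = rev.sort_values(kind="mergesort").index
        assert list(order_fwd) == list(order_rev[::-1])


def _oracle_pipeline(counts, samples, lib_frame, tpm, pseudocount, minus, plus):
    """Single nested-loop re-implementation of the five scoring stages."""
    rpm = {}
    for s in counts.columns:
        total = sum(counts[s])
        rpm[s] = {g: counts.loc[g, s] / total * 1e6 for g in counts.index}
    base = [s for s in counts.columns if samples.loc[s, "condition"] == BASELINE]
    lfc = {}
    for s in counts.columns:
        if s in base:
            continue
        rep = samples.loc[s, "replicate"]
        matched = [b for b in base if samples.loc[b, "replicate"] == rep] or base
        lfc[s] = {}
        for g in counts.index:
            ref = sum(rpm[b][g] for b in matched) / len(matched)
            lfc[s][g] = math.log2(rpm[s][g] + pseudocount) - math.log2(ref + pseudocount)
    genes = sorted(set(lib_frame.loc[g, "gene"] for g in counts.index
                       if not lib_frame.loc[g, "is_control"]))
    scores = {}
    for cond in (minus, plus):
        cond_samples = [s for s in lfc if samples.loc[s, "condition"] == cond]
        reps = sorted({samples.loc[s, "replicate"] for s in cond_samples})
        for gene in genes:
            guides = [g for g in counts.index
                      if lib_frame.loc[g, "gene"] == gene
                      and not lib_frame.loc[g, "is_control"]]
            rep_means = []
            for r in reps:
                cols = [s for s in cond_samples if samples.loc[s, "replicate"] == r]
                per_guide = [sum(lfc[s][g] for s in cols) / len(cols)
                             for g in guides]
                rep_means.append(sum(per_guide) / len(per_guide))
            scores[(gene, cond)] = sum(rep_means) / len(rep_means)
    out = {}
    for cond in (minus, plus):
        null_vals = [scores[(g, cond)] for g in genes if tpm[g] < 1.0]
        mu = sum(null_vals) / len(null_vals)
        var = sum((v - mu) ** 2 for v in null_vals) / (len(null_vals) - 1)
        sdv = math.sqrt(var)
        for g in genes:
            out[(g, "Z_" + cond)] = (scores[(g, cond)] - mu) / sdv
    for g in genes:
        out[(g, "delta_z")] = out[(g, "Z_" + minus)] - out[(g, "Z_" + plus)]
    return out


def test_pipeline_matches_brute_force_oracle(tiny_samples):
    rng = np.random.default_rng(7)
    genes = [f"G{i:02d}" for i in range(20)]
    rows = [(f"{g}_sg{j}", g, False) for g in genes for j in range(3)]
    rows.append(("CTRL_sg0", "control", True))
    lib_frame = pd.DataFrame(
        {"gene": [r[1] for r in rows], "is_control": [r[2] for r in rows]},
        index=pd.Index([r[0] for r in rows], name="guide_id"),
    )
    library = sd.GuideLibrary(lib_frame)
    counts = pd.DataFrame(
        rng.integers(10, 2000, size=(len(rows), len(tiny_samples))),
        index=lib_frame.index, columns=tiny_samples.index, dtype=np.int64,
    )
    tpm = {g: (0.2 if i < 5 else 50.0) for i, g in enumerate(genes)}
    expr = sd.ExpressionTable(pd.Series(tpm).rename_axis("gene"))
    res = sd.ConditionalEssentiality(
        sd.CountMatrix(counts, tiny_samples), library, expr
    ).fit()
    oracle = _oracle_pipeline(counts, tiny_samples, lib_frame, tpm, 1.0,
                              "minus_uridine", "plus_uridine")
    for g in genes:
        assert res.table.loc[g, "Z_minus"] == pytest.approx(
            oracle[(g, "Z_minus_uridine")], abs=1e-12)
        assert res.table.loc[g, "Z_plus"] == pytest.approx(
            oracle[(g, "Z_plus_uridine")], abs=1e-12)
        assert res.table.loc[g, "delta_z"] == pytest.approx(
            oracle[(g, "delta_z")], abs=1e-12)


def test_results_surface(tiny_counts, tiny_library, tmp_path):
    expr = sd.ExpressionTable(pd.Series(
        {"A": 0.2, "B": 0.4}).rename_axis("gene"))
    # two genes both below TPM 1: every gene is a null gene, ranked() is empty
    res = sd.ConditionalEssentiality(tiny_counts, tiny_library, expr).fit()
    assert res.table["is_null_gene"].all()
    assert res.ranked().empty
    assert "empirical null" in res.summary()
    out = tmp_path / "scores.tsv"
    res.to_tsv(out)
    assert out.read_text().startswith("gene\t")
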