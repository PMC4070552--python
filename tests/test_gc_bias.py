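"""GC regressions, AIC comparison, AT/GC t-test and the site-level ANCOVA."""

import numpy as np
import pandas as pd
import pytest

from mitocovbias import (
    SimulationConfig,
    at_gc_coverage_ttest,
    compare_models_aic,
    fit_gc_regression,
    generate_reference,
    simulate_site_profiles,
    site_ancova,
    site_gc50,
    window_profile,
)


def _table(gc, y):
    return pd.DataFrame({"gc": gc, "mean_cov": y})


class TestFitGcRegression:
    def test_exact_line(self):
        fit = fit_gc_regression(_table([0.2, 0.4, 0.6], [10, 20, 30]), 1)
        assert fit.coefficients[1] == pytest.approx(50)
        assert fit.R2 == pytest.approx(1)
        assert fit.rss == pytest.approx(0, abs=1e-18)
        assert fit.df == 1

    def test_exact_quadratic_vertex_at_zero(self):
        gc = [0.1, 0.2, 0.3, 0.4, 0.5]
        y = [(10 * g) ** 2 for g in gc]
        fit = fit_gc_regression(_table(gc, y), 2)
        assert fit.coefficients[2] == pytest.approx(100)
        assert fit.vertex_gc == pytest.approx(0, abs=1e-9)
        assert fit.R2 == pytest.approx(1)

    def test_quadratic_never_fits_worse_than_linear(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            gc = rng.uniform(0.2, 0.6, 40)
            y = 100 - 50 * gc + rng.normal(0, 5, 40)
            t = _table(gc, y)
            assert fit_gc_regression(t, 2).rss <= fit_gc_regression(t, 1).rss + 1e-9

    def test_fitted_values_invariant_to_affine_gc_rescale(self):
        rng = np.random.default_rng(5)
        gc = rng.uniform(0.2, 0.6, 60)
        y = 120 - 80 * gc + 40 * gc**2 + rng.normal(0, 3, 60)
        for degree in (1, 2):
            f0 = fit_gc_regression(_table(gc, y), degree)
            f1 = fit_gc_regression(_table(2.5 * gc - 0.4, y), degree)
            X0 = np.column_stack([gc**d for d in range(degree + 1)])
            X1 = np.column_stack([(2.5 * gc - 0.4) ** d for d in range(degree + 1)])
            assert np.allclose(X0 @ f0.coefficients, X1 @ f1.coefficients)
            assert f0.R2 == pytest.approx(f1.R2)

    def test_vertex_recovery_from_generator_model(self):
        """Quadratic fit of window-mean log coverage on window-mean gc50
        recovers the generating vertex within +-0.03 at ~300 windows."""
        cfg = SimulationConfig(seed=2, n_individuals=1, n_heteroplasmic=0)
        ref, motifs = generate_reference(cfg)
        profiles, _ = simulate_site_profiles(ref, cfg, motifs)
        cov = profiles[0].depth.astype(float)
        gc50 = site_gc50(ref.sequence, 50)
        w = 50
        nwin = len(cov) // w
        table = _table(
            gc50[: nwin * w].reshape(nwin, w).mean(axis=1),
            np.log(np.maximum(cov[: nwin * w], 1)).reshape(nwin, w).mean(axis=1),
        )
        fit = fit_gc_regression(table, 2)
        assert fit.n >= 300
        assert fit.vertex_gc == pytest.approx(cfg.vertex_gc, abs=0.03)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            fit_gc_regression(_table([0.3, 0.3, 0.3], [1, 2, 3]), 1)
        with pytest.raises(ValueError, match="windows"):
            fit_gc_regression(_table([0.1, 0.2], [1, 2]), 1)


class TestCompareModelsAic:
    def test_noiseless_linear_penalizes_extra_parameter(self):
        t = _table([0.1, 0.2, 0.3, 0.4, 0.5], [1, 2, 3, 4, 5])
        delta = compare_models_aic(fit_gc_regression(t, 1), fit_gc_regression(t, 2))
        # both RSS hit the epsilon floor; only the parameter count differs
        assert delta == pytest.approx(2.0)

    def test_noiseless_quadratic_strongly_favored(self):
        gc = np.linspace(0.1, 0.6, 30)
        t = _table(gc, 5 + 100 * (gc - 0.3) ** 2)
        delta = compare_models_aic(fit_gc_regression(t, 1), fit_gc_regression(t, 2))
        assert delta < -50

    def test_identical_fits_give_zero(self):
        t = _table([0.1, 0.25, 0.4, 0.55], [4, 3, 2.5, 1])
        f = fit_gc_regression(t, 1)
        assert compare_models_aic(f, f) == 0

    def test_sample_size_mismatch_rejected(self):
        f1 = fit_gc_regression(_table([0.1, 0.2, 0.3, 0.4], [1, 2, 3, 4]), 1)
        f2 = fit_gc_regression(_table([0.1, 0.2, 0.3, 0.4, 0.5], [1, 2, 3, 4, 5]), 2)
        with pytest.raises(ValueError):
            compare_models_aic(f1, f2)


class TestAtGcCoverageTtest:
    def test_equal_groups_give_zero_t(self):
        t, df, p, m_at, m_gc = at_gc_coverage_ttest(np.full(8, 10.0), "AATTGGCC")
        assert t == 0
        assert m_at == m_gc == 10

    def test_sign_convention_at_minus_gc(self):
        cov = np.array([12.0, 12, 12, 12, 10, 10, 10, 10])
        t, _, _, m_at, m_gc = at_gc_coverage_ttest(cov, "ATATGCGC")
        assert m_at - m_gc == pytest.approx(2)
        assert t > 1e3  # variance floor keeps the statistic finite but huge

    def test_matches_brute_force_welch_formula(self):
        rng = np.random.default_rng(21)
        cov = rng.uniform(50, 150, 200)
        seq = "".join(rng.choice(list("ACGT"), 200))
        t, df, p, m_at, m_gc = at_gc_coverage_ttest(cov, seq)
        is_at = np.isin(list(seq), ["A", "T"])
        a, g = cov[is_at], cov[~is_at]
        v1, v2 = a.var(ddof=1), g.var(ddof=1)
        se2 = v1 / len(a) + v2 / len(g)
        t_ref = (a.mean() - g.mean()) / np.sqrt(se2)
        df_ref = se2**2 / (
            (v1 / len(a)) ** 2 / (len(a) - 1) + (v2 / len(g)) ** 2 / (len(g) - 1)
        )
        assert t == pytest.approx(t_ref, abs=1e-10)
        assert df == pytest.approx(df_ref, abs=1e-8)

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError):
            at_gc_coverage_ttest(np.ones(3), "AAG")


class TestSiteAncova:
    def test_planted_continuous_effect_recovered_exactly(self):
        rng = np.random.default_rng(9)
        n = 400
        gc50 = rng.uniform(0.2, 0.6, n)
        cov = 100 - 50 * gc50
        bases = rng.choice(list("ACGT"), n)
        genes = rng.choice(["protein_coding", "tRNA", "rRNA", "intergenic"], n)
        res = site_ancova(cov, bases, genes, gc50)
        assert res["coefficients"]["gc50"] == pytest.approx(-50, abs=1e-8)
        anova = res["anova"]
        assert anova.loc["gc50", "F"] > 1e6
        # residual variance is ~0 for the exact fit, so compare explained SS
        assert anova.loc["C(base)", "sum_sq"] < 1e-9 * anova.loc["gc50", "sum_sq"]

    def test_planted_gene_type_offsets_recovered(self):
        rng = np.random.default_rng(17)
        n = 15_000
        gc50 = rng.uniform(0.25, 0.55, n)
        genes = rng.choice(["protein_coding", "rRNA", "tRNA"], n)
        offset = np.select(
            [genes == "protein_coding", genes == "rRNA"], [5.0, -5.0], 0.0
        )
        cov = 100 - 30 * gc50 + offset + rng.normal(0, 10, n)
        bases = rng.choice(list("ACGT"), n)
        res = site_ancova(cov, bases, genes, gc50)
        fit = res["model"]
        # treatment coding: reference level protein_coding (alphabetical)
        ci = fit.conf_int()
        assert ci.loc["C(gene_type)[T.rRNA]", 0] < -10 < ci.loc["C(gene_type)[T.rRNA]", 1]
        assert ci.loc["C(gene_type)[T.tRNA]", 0] < -5 < ci.loc["C(gene_type)[T.tRNA]", 1]

    def test_single_level_term_rejected(self):
        with pytest.raises(ValueError, match="gene_type"):
            site_ancova(
                np.ones(10),
                np.array(list("ACGTACGTAC")),
                np.array(["tRNA"] * 10),
                np.linspace(0.2, 0.6, 10),
            )


class TestSiteGc50:
    def test_matches_direct_window_count(self):
        seq = "GGGGGAAAAATTTTTCCCCC"
        gc = site_gc50(seq, 4)
        # site 10: window [8, 12) = 'AATT' -> 0 GC
        assert gc[10] == 0.0
        # site 2: window [0, 4) = 'GGGG'
        assert gc[2] == 1.0

    def test_edges_truncated_not_padded(self):
        gc = site_gc50("GCAT", 50)
        assert np.allclose(gc, 0.5)  # whole sequence is the window everywhere
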