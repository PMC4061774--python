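"""Per-gene screening, concordance, and the factorial count model."""

import itertools

import numpy as np
import pandas as pd
import pytest

import sigensemble as se
from sigensemble.assessment import (
    CountModelSpec,
    build_prognosis_table,
    design_matrix,
    fit_count_model,
    gaussian_aic,
    per_gene_prognosis,
    pipeline_concordance,
    significance_summary,
    stepwise_aic_backward,
)
from sigensemble.exceptions import ModelError


@pytest.fixture(scope="module")
def screen_cohort():
    cfg = se.SimulationConfig(
        n_patients=500, n_genes=40, signature_size=1,
        effect_size=3.0, log_hazard_beta=1.5, seed=21,
    )
    return se.simulate_cohort(cfg)


class TestPerGenePrognosis:
    def test_planted_prognostic_gene_attains_smallest_q(self, screen_cohort):
        tab = per_gene_prognosis(
            screen_cohort.base_expression, screen_cohort.survival
        )
        planted = screen_cohort.signature_genes[0]
        assert tab["q"].idxmin() == planted
        assert tab.loc[planted, "hr"] > 1.0

    def test_null_screen_rarely_flags_anything(self):
        cfg = se.SimulationConfig(
            n_patients=120, n_genes=150, signature_size=1,
            effect_size=0.0, log_hazard_beta=0.0, seed=5,
        )
        cohort = se.simulate_cohort(cfg)
        tab = per_gene_prognosis(cohort.base_expression, cohort.survival)
        assert (tab["q"] <= 0.05).sum() == 0

    def test_constant_gene_yields_flagged_na_row(self, screen_cohort):
        mat = screen_cohort.base_expression.iloc[:5].copy()
        mat.loc["G0001"] = 7.0  # constant expression: everyone below-or-at median
        tab = per_gene_prognosis(mat, screen_cohort.survival)
        assert not tab.loc["G0001", "estimable"]
        assert np.isnan(tab.loc["G0001", "q"])
        # the NA row is excluded from the FDR input
        est = tab[tab["estimable"]]
        np.testing.assert_allclose(est["q"], se.bh_fdr(est["p"]))

    def test_identical_across_log2_pair(self, small_cohort, full_views):
        pair = [v for v in full_views if v.algorithm in ("MAS5", "log2MAS5")
                and v.annotation == "default" and v.handling == "merged"]
        tabs = [
            per_gene_prognosis(full_views[v].iloc[:10], small_cohort.survival)
            for v in pair
        ]
        pd.testing.assert_frame_equal(tabs[0], tabs[1])


class TestSignificanceSummary:
    def make_table(self, q_matrix):
        rows = []
        for gi, row in enumerate(q_matrix):
            for vi, q in enumerate(row):
                rows.append({"gene": f"G{gi}", "variant": f"v{vi}", "q": q})
        return pd.DataFrame(rows)

    def test_all_insignificant_gives_zero_counts(self):
        out = significance_summary(self.make_table(np.ones((4, 3))))
        assert (out["per_variant"] == 0).all()
        assert (out["per_gene"] == 0).all()

    def test_gene_significant_in_12_of_24_variants(self):
        q = np.ones((1, 24))
        q[0, :12] = 0.01
        out = significance_summary(self.make_table(q))
        assert out["per_gene"]["G0"] == 12

    @pytest.mark.parametrize("seed", range(3))
    def test_marginals_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        q = rng.random((20, 6))
        out = significance_summary(self.make_table(q), alpha=0.3)
        ind = q <= 0.3
        np.testing.assert_array_equal(
            out["per_variant"].to_numpy(), ind.sum(axis=0)
        )
        np.testing.assert_array_equal(out["per_gene"].to_numpy(), ind.sum(axis=1))


class TestPipelineConcordance:
    def test_duplicated_variant_gives_unit_correlation(self):
        rng = np.random.default_rng(1)
        q = rng.random(30)
        tab = pd.DataFrame(
            {"gene": [f"G{i}" for i in range(30)] * 2,
             "variant": ["a"] * 30 + ["b"] * 30,
             "q": np.concatenate([q, q])}
        )
        mat = pipeline_concordance(tab)
        assert mat.loc["a", "b"] == pytest.approx(1.0)
        assert (np.diag(mat) == 1.0).all()

    def test_independent_columns_weakly_correlated(self):
        rng = np.random.default_rng(2)
        genes = [f"G{i}" for i in range(500)]
        tab = pd.concat([
            pd.DataFrame({"gene": genes, "variant": v, "q": rng.random(500)})
            for v in ("a", "b")
        ])
        rho = pipeline_concordance(tab).loc["a", "b"]
        assert abs(rho) < 0.3

    def test_matches_elementwise_spearman_and_is_symmetric(self):
        rng = np.random.default_rng(3)
        genes = [f"G{i}" for i in range(25)]
        tab = pd.concat([
            pd.DataFrame({"gene": genes, "variant": v, "q": rng.random(25)})
            for v in ("a", "b", "c")
        ])
        mat = pipeline_concordance(tab)
        wide = tab.pivot(index="gene", columns="variant", values="q")
        for va, vb in itertools.combinations(wide.columns, 2):
            assert mat.loc[va, vb] == pytest.approx(
                se.spearman(wide[va], wide[vb])
            )
            assert mat.loc[va, vb] == mat.loc[vb, va]

    def test_too_few_shared_genes_is_na(self):
        tab = pd.DataFrame({
            "gene": ["G0", "G1", "G0", "G1"],
            "variant": ["a", "a", "b", "b"],
            "q": [0.1, 0.2, 0.3, 0.4],
        })
        assert np.isnan(pipeline_concordance(tab).loc["a", "b"])


def factorial_counts(rng=None, noise=0.0, platform_effect=30.0):
    """48-row design (24 variants x 2 platforms) with known structure."""
    rows = []
    for v in se.full_factorial_design():
        for platform in ("HG-U133A", "HG-U133 Plus 2.0"):
            y = 100.0
            y += 20.0 * (v.annotation == "default")
            y += platform_effect * (platform == "HG-U133 Plus 2.0")
            y += 10.0 * (v.handling == "separate")
            if rng is not None and noise:
                y += rng.normal(0, noise)
            rows.append({
                "annotation": v.annotation, "platform": platform,
                "handling": v.handling, "algorithm": v.algorithm,
                "n_significant": y,
            })
    return pd.DataFrame(rows)


class TestCountModel:
    def test_exact_linear_data_recovers_coefficients(self):
        data = factorial_counts()
        fit = fit_count_model(data, CountModelSpec())
        coefs = fit.coefficients["estimate"]
        assert coefs["annotation[default]"] == pytest.approx(20.0, abs=1e-8)
        assert coefs["platform[HG-U133 Plus 2.0]"] == pytest.approx(30.0, abs=1e-8)
        assert coefs["handling[separate]"] == pytest.approx(10.0, abs=1e-8)
        assert fit.r_squared_adjusted == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_normal_equations_oracle(self, seed):
        rng = np.random.default_rng(seed)
        data = factorial_counts(rng, noise=25.0)
        spec = CountModelSpec.full_pairwise()
        fit = fit_count_model(data, spec)
        X = design_matrix(data, spec).to_numpy()
        y = data["n_significant"].to_numpy()
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(
            fit.coefficients["estimate"].to_numpy(), beta, atol=1e-8
        )

    def test_table_layout(self):
        fit = fit_count_model(factorial_counts(), CountModelSpec())
        assert list(fit.coefficients.columns) == ["estimate", "se", "t", "p"]
        # intercept + 1 + 1 + 1 + 5 algorithm dummies
        assert len(fit.coefficients) == 9

    def test_constant_response_intercept_only(self):
        data = factorial_counts(platform_effect=0.0)
        data["n_significant"] = 42.0
        spec = CountModelSpec(main_effects=(), interactions=())
        fit = fit_count_model(data, spec)
        assert fit.coefficients["estimate"]["(Intercept)"] == pytest.approx(42.0)
        assert fit.rss == pytest.approx(0.0, abs=1e-16)

    def test_rank_deficiency_names_aliased_terms(self):
        data = factorial_counts()
        data["platform"] = "HG-U133A"  # collapses a factor
        spec = CountModelSpec(
            baselines={**CountModelSpec().baselines},
        )
        with pytest.raises(ModelError):
            fit_count_model(data.assign(annotation=data["handling"].map(
                {"separate": "default", "merged": "alternative"})), spec)


def exhaustive_best_aic(data, spec):
    """Independent oracle: evaluate AIC of every marginality-respecting
    sub-model reachable by deletions and return the minimum."""
    best = fit_count_model(data, spec).aic
    frontier = [spec]
    seen = {(spec.main_effects, spec.interactions)}
    while frontier:
        cur = frontier.pop()
        in_inter = {f for pair in cur.interactions for f in pair}
        terms = list(cur.interactions) + [
            f for f in cur.main_effects if f not in in_inter
        ]
        for term in terms:
            nxt = cur.drop_term(term)
            key = (nxt.main_effects, nxt.interactions)
            if key in seen:
                continue
            seen.add(key)
            best = min(best, fit_count_model(data, nxt).aic)
            frontier.append(nxt)
    return best


class TestStepwiseAic:
    def test_main_effects_data_keeps_mains_and_prunes_most_interactions(self):
        """On main-effects-only data the stepwise drops most interaction
        blocks and never drops a true main effect.

        AIC is not consistent: a null 1-df interaction survives with
        probability ~P(chi2_1 > 2) ~ 0.16, so full pruning of all six
        blocks happens in only roughly half the seeds; the robust property
        is the expected count, not all-or-nothing pruning.
        """
        kept_counts = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            data = factorial_counts(rng, noise=10.0)
            spec, fit = stepwise_aic_backward(
                data, CountModelSpec.full_pairwise()
            )
            kept_counts.append(len(spec.interactions))
            # strong true main effects always retained
            for f in ("annotation", "platform", "handling"):
                assert f in spec.main_effects
        assert np.mean(kept_counts) <= 2.5  # most of the 6 blocks pruned

    def test_result_aic_never_above_full_model(self):
        rng = np.random.default_rng(42)
        data = factorial_counts(rng, noise=40.0)
        full = fit_count_model(data, CountModelSpec.full_pairwise())
        _, fit = stepwise_aic_backward(data, CountModelSpec.full_pairwise())
        assert fit.aic <= full.aic + 1e-9

    def test_null_term_removed_first_and_optimum_reached(self):
        # annotation has zero true effect; restrict to two factors so the
        # exhaustive-subset oracle is cheap
        rng = np.random.default_rng(7)
        data = factorial_counts(rng, noise=5.0)
        data["n_significant"] -= 20.0 * (data["annotation"] == "default")
        spec = CountModelSpec(
            main_effects=("annotation", "handling"),
            interactions=(("annotation", "handling"),),
        )
        out_spec, fit = stepwise_aic_backward(data, spec)
        assert ("annotation", "handling") not in out_spec.interactions
        assert fit.aic == pytest.approx(exhaustive_best_aic(data, spec), abs=1e-9)

    def test_marginality_respected_on_randomized_runs(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            data = factorial_counts(rng, noise=60.0)
            spec, _ = stepwise_aic_backward(data, CountModelSpec.full_pairwise())
            retained = {f for pair in spec.interactions for f in pair}
            assert retained <= set(spec.main_effects)

    def test_aic_formula(self):
        assert gaussian_aic(np.e**2 * 10, 10, 3) == pytest.approx(
            10 * 2 + 2 * 4
        )


class TestBuildPrognosisTable:
    def test_stacks_variants_long(self, small_cohort, full_views):
        keys = list(full_views)[:2]
        per_variant = {
            k.key: per_gene_prognosis(full_views[k].iloc[:5], small_cohort.survival)
            for k in keys
        }
        tab = build_prognosis_table(per_variant)
        assert set(tab.columns) >= {"gene", "variant", "hr", "p", "q", "estimable"}
        assert len(tab) == 10
        assert set(tab["variant"]) == {k.key for k in keys}
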