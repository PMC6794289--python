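import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest

from pmrna import pmi
from pmrna.exceptions import ValidationError
from pmrna.pmi import CtPanel, PmiEnsemble, PmiModel


def panel_from_wide(ct_wide: pd.DataFrame, pmi_by_animal: dict) -> CtPanel:
    """Build a raw CtPanel from an animals x genes Ct matrix."""
    records = [
        {"gene_id": g, "animal_id": a, "pmi_hours": float(pmi_by_animal[a]),
         "ct": float(ct_wide.loc[a, g])}
        for a in ct_wide.index for g in ct_wide.columns
    ]
    return CtPanel(pd.DataFrame(records))


def linear_rule_panel(n_per_tp=4, seed=0, noise=0.0):
    """Noise-free-capable panel where PMI = 2 * dCt of gene gA by construction.

    Zero-mean rows are used as raw Ct so that delta-Ct equals the
    constructed values exactly after normalisation.
    """
    rng = np.random.default_rng(seed)
    pmis = np.repeat([0.0, 6.0, 12.0, 18.0, 24.0], n_per_tp)
    animals = [f"A{i:02d}" for i in range(pmis.size)]
    genes = ["gA", "gB", "gC", "gD", "gE"]
    raw = rng.normal(0, 1, size=(pmis.size, len(genes)))
    raw[:, 0] = pmis / 2.0                 # exact linear rule via gA
    raw[:, -1] = -raw[:, :-1].sum(axis=1)  # zero row mean -> delta-Ct == raw Ct
    if noise:
        raw += rng.normal(0, noise, raw.shape)
    ct_wide = pd.DataFrame(raw, index=animals, columns=genes)
    return panel_from_wide(ct_wide, dict(zip(animals, pmis)))


def exact_linear_panel(n_per_tp=4, seed=0, n_genes=6):
    """Panel where every 3-gene model fits PMI exactly.

    Each gene's Ct is a fixed linear combination of PMI and two shared
    latent components, so PMI lies in the span of any non-singular triple
    of (centered) delta-Ct columns plus an intercept.
    """
    rng = np.random.default_rng(seed)
    pmis = np.repeat([0.0, 6.0, 12.0, 18.0, 24.0], n_per_tp)
    animals = [f"A{i:02d}" for i in range(pmis.size)]
    w1 = rng.normal(0, 1, pmis.size)
    w2 = rng.normal(0, 1, pmis.size)
    coef = rng.normal(0, 1, size=(n_genes, 3))
    raw = (coef[:, 0][None, :] * pmis[:, None]
           + coef[:, 1][None, :] * w1[:, None]
           + coef[:, 2][None, :] * w2[:, None]) + 25.0
    ct_wide = pd.DataFrame(raw, index=animals,
                           columns=[f"g{i}" for i in range(n_genes)])
    return panel_from_wide(ct_wide, dict(zip(animals, pmis)))


class TestNormalize:
    def test_hand_arithmetic(self):
        ct = pd.DataFrame([[20.0, 22.0, 24.0]], index=["A1"], columns=["g1", "g2", "g3"])
        panel = panel_from_wide(ct, {"A1": 0.0}).normalize()
        delta = panel.wide_delta()
        np.testing.assert_allclose(delta.loc["A1"], [-2.0, 0.0, 2.0], atol=1e-12)

    def test_per_animal_shift_invariance(self):
        rng = np.random.default_rng(1)
        ct = pd.DataFrame(rng.uniform(18, 30, (3, 4)), index=["A1", "A2", "A3"],
                          columns=list("abcd"))
        base = panel_from_wide(ct, {"A1": 0, "A2": 6, "A3": 12}).normalize()
        shifted = ct.copy()
        shifted.loc["A2"] += 5.0
        after = panel_from_wide(shifted, {"A1": 0, "A2": 6, "A3": 12}).normalize()
        pd.testing.assert_frame_equal(base.wide_delta(), after.wide_delta())

    def test_single_gene_panel_is_all_zero(self):
        ct = pd.DataFrame([[20.0], [25.0]], index=["A1", "A2"], columns=["g1"])
        panel = panel_from_wide(ct, {"A1": 0, "A2": 6}).normalize()
        np.testing.assert_allclose(panel.wide_delta().to_numpy(), 0.0, atol=1e-12)

    def test_delta_means_are_zero_per_animal(self, marker_panel):
        norm = marker_panel.normalize()
        means = norm.data.groupby("animal_id")["delta_ct"].mean()
        np.testing.assert_allclose(means.to_numpy(), 0.0, atol=1e-9)

    def test_double_normalisation_rejected(self, marker_panel):
        norm = marker_panel.normalize()
        with pytest.raises(ValidationError, match="already normalized"):
            norm.normalize()

    def test_incomplete_panel_lists_missing_pairs(self):
        ct = pd.DataFrame([[20.0, 21.0], [22.0, 23.0]], index=["A1", "A2"],
                          columns=["g1", "g2"])
        records = panel_from_wide(ct, {"A1": 0, "A2": 6}).data.iloc[:-1]
        with pytest.raises(ValidationError, match="A2"):
            CtPanel(records)


class TestEnumerateTriples:
    def test_eighteen_genes_give_816(self):
        triples = pmi.enumerate_triples([f"g{i:02d}" for i in range(18)])
        assert len(triples) == 816 == comb(18, 3)

    def test_minimum_three_genes(self):
        assert pmi.enumerate_triples(["c", "a", "b"]) == [("a", "b", "c")]
        with pytest.raises(ValidationError):
            pmi.enumerate_triples(["a", "b"])

    def test_matches_itertools_oracle_small_n(self):
        for n in range(3, 7):
            genes = [f"g{i}" for i in range(n)]
            expected = sorted(itertools.combinations(sorted(genes), 3))
            assert pmi.enumerate_triples(genes) == expected

    @pytest.mark.parametrize("n", range(3, 21))
    def test_count_matches_binomial_formula(self, n):
        assert len(pmi.enumerate_triples([f"g{i:02d}" for i in range(n)])) == comb(n, 3)


class TestFitEnsemble:
    def test_exact_linear_rule_recovered(self):
        panel = linear_rule_panel(seed=2)
        ensemble = pmi.fit_ensemble(panel.normalize(), p_threshold=0.05)
        with_ga = [m for m in ensemble.models if "gA" in m.genes]
        assert with_ga, "models containing the signal gene must be retained"
        for m in with_ga:
            assert m.r2 == pytest.approx(1.0, abs=1e-9)
            assert m.model_p == pytest.approx(0.0, abs=1e-12)
        # a triple of gA with two noise genes recovers the coefficient 2 h/cycle
        solo = [m for m in with_ga if m.r2 > 0.999999]
        coefs = [m.coefficients[m.genes.index("gA")] for m in solo]
        np.testing.assert_allclose(coefs, 2.0, atol=1e-6)

    def test_threshold_one_retains_all_nonsingular(self):
        panel = linear_rule_panel(seed=3).normalize()
        ensemble = pmi.fit_ensemble(panel, p_threshold=1.0)
        assert len(ensemble) + ensemble.n_skipped_singular == comb(5, 3)

    def test_null_panel_retention_near_threshold(self):
        rng = np.random.default_rng(4)
        animals = [f"A{i:02d}" for i in range(30)]
        ct = pd.DataFrame(rng.normal(25, 1, (30, 10)), index=animals,
                          columns=[f"g{i}" for i in range(10)])
        pmis = dict(zip(animals, rng.permutation(np.repeat([0, 6, 12, 18, 24], 6))))
        panel = panel_from_wide(ct, pmis).normalize()
        ensemble = pmi.fit_ensemble(panel, p_threshold=0.05)
        frac = len(ensemble) / ensemble.n_candidates
        assert 0.005 < frac < 0.15   # ~ nominal rate, wide MC slack (models correlate)

    def test_direction_flag_flips_retention(self):
        panel = linear_rule_panel(seed=5).normalize()
        le = pmi.fit_ensemble(panel, p_threshold=0.05, direction="le")
        ge = pmi.fit_ensemble(panel, p_threshold=0.05, direction="ge")
        n_ok = le.n_candidates - le.n_skipped_singular
        assert len(le) + len(ge) >= n_ok  # boundary models may land in both
        assert {tuple(m.genes) for m in le.models}.isdisjoint(
            {tuple(m.genes) for m in ge.models if m.model_p > 0.05})

    def test_too_few_animals_rejected(self):
        ct = pd.DataFrame(np.random.default_rng(0).normal(25, 1, (4, 5)),
                          index=[f"A{i}" for i in range(4)], columns=list("abcde"))
        panel = panel_from_wide(ct, {f"A{i}": 6 * i for i in range(4)})
        with pytest.raises(ValidationError, match="5 animals"):
            pmi.fit_ensemble(panel)


class TestPredict:
    def _toy_ensemble(self):
        m1 = PmiModel(genes=("a", "b", "c"), intercept=5.0, coefficients=(0.0, 0.0, 0.0),
                      model_p=0.01, r2=0.9)
        m2 = PmiModel(genes=("a", "b", "d"), intercept=7.0, coefficients=(0.0, 0.0, 0.0),
                      model_p=0.01, r2=0.9)
        return m1, m2

    def _flat_panel(self):
        ct = pd.DataFrame(np.zeros((1, 4)), index=["A1"], columns=list("abcd"))
        return panel_from_wide(ct, {"A1": 0.0}).normalize()

    def test_mean_of_two_models(self):
        m1, m2 = self._toy_ensemble()
        ensemble = PmiEnsemble(models=[m1, m2], p_threshold=0.05)
        pred = pmi.predict_pmi(ensemble, self._flat_panel())
        assert pred.estimates["A1"] == pytest.approx(6.0)

    def test_single_model_identity(self):
        m1, _ = self._toy_ensemble()
        pred = pmi.predict_pmi(PmiEnsemble(models=[m1], p_threshold=0.05),
                               self._flat_panel())
        assert pred.estimates["A1"] == pytest.approx(5.0)

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValidationError, match="no retained models"):
            pmi.predict_pmi(PmiEnsemble(models=[], p_threshold=0.05), self._flat_panel())

    def test_missing_gene_rejected(self):
        m1, _ = self._toy_ensemble()
        ct = pd.DataFrame(np.zeros((1, 2)), index=["A1"], columns=["a", "b"])
        panel = panel_from_wide(ct, {"A1": 0.0}).normalize()
        with pytest.raises(ValidationError, match="missing genes"):
            pmi.predict_pmi(PmiEnsemble(models=[m1], p_threshold=0.05), panel)

    def test_noise_free_exact_recovery(self):
        panel = exact_linear_panel(seed=6).normalize()
        ensemble = pmi.fit_ensemble(panel, p_threshold=0.05)
        pred = pmi.predict_pmi(ensemble, panel)
        truth = panel.pmi_by_animal().loc[pred.estimates.index]
        np.testing.assert_allclose(pred.estimates, truth, atol=1e-6)

    def test_model_and_animal_order_invariance(self):
        panel = linear_rule_panel(seed=7, noise=0.2).normalize()
        ensemble = pmi.fit_ensemble(panel, p_threshold=1.0)
        pred = pmi.predict_pmi(ensemble, panel)
        shuffled = PmiEnsemble(models=list(reversed(ensemble.models)),
                               p_threshold=1.0)
        rev_animals = panel.subset_animals(list(reversed(panel.animals)))
        pred2 = pmi.predict_pmi(shuffled, rev_animals)
        pd.testing.assert_series_equal(pred.estimates.sort_index(),
                                       pred2.estimates.sort_index())


class TestLoao:
    def test_noise_free_linear_panel_near_zero_error(self):
        panel = exact_linear_panel(seed=8)
        result = pmi.evaluate_loao(panel.normalize())
        assert result.mae < 1e-6

    def test_planted_panel_mae_below_two_hours(self, marker_panel):
        result = pmi.evaluate_loao(marker_panel.normalize())
        assert result.mae < 2.0
        assert result.rmse >= result.mae

    def test_shuffled_labels_degrade_to_baseline(self, marker_panel):
        norm = marker_panel.normalize()
        rng = np.random.default_rng(9)
        truth = norm.pmi_by_animal()
        shuffled = pd.Series(rng.permutation(truth.to_numpy()), index=truth.index)
        data = norm.data.copy()
        data["pmi_hours"] = data["animal_id"].map(shuffled)
        scrambled = CtPanel(data, normalized=True)
        result = pmi.evaluate_loao(scrambled)
        # grand-mean predictor MAE on the 0..24 grid is 7.2 h; shuffled labels
        # should be in that regime, far above the signal fit
        baseline_mae = float(np.abs(truth - truth.mean()).mean())
        assert result.mae > 0.5 * baseline_mae

    def test_too_few_animals_rejected(self):
        ct = pd.DataFrame(np.random.default_rng(0).normal(25, 1, (5, 4)),
                          index=[f"A{i}" for i in range(5)], columns=list("abcd"))
        panel = panel_from_wide(ct, {f"A{i}": 6 * i for i in range(5)})
        with pytest.raises(ValidationError, match="6 animals"):
            pmi.evaluate_loao(panel.normalize())


class TestFacadeAndIO:
    def test_results_roundtrip_through_tsv(self, tmp_path, marker_panel):
        fit = pmi.PmiEnsembleModel(marker_panel).fit()
        path = tmp_path / "models.tsv"
        pmi.write_models_tsv(fit, path)
        loaded = pmi.read_models_tsv(path)
        assert len(loaded) == len(fit.ensemble)
        pred_a = pmi.predict_pmi(fit.ensemble, fit.model.panel).estimates
        pred_b = pmi.predict_pmi(loaded, fit.model.panel).estimates
        np.testing.assert_allclose(pred_a, pred_b, rtol=1e-9)

    def test_summary_mentions_candidates_and_threshold(self, marker_panel):
        fit = pmi.PmiEnsembleModel(marker_panel).fit()
        text = fit.summary()
        assert "816" in text and "0.05" in text

    def test_ols_p_matches_statsmodels(self):
        import statsmodels.api as sm
        panel = linear_rule_panel(seed=11, noise=1.0).normalize()
        ensemble = pmi.fit_ensemble(panel, p_threshold=1.0)
        delta = panel.wide_delta()
        y = panel.pmi_by_animal().loc[delta.index].to_numpy()
        m = ensemble.models[0]
        sm_fit = sm.OLS(y, sm.add_constant(delta[list(m.genes)].to_numpy())).fit()
        assert m.model_p == pytest.approx(sm_fit.f_pvalue, rel=1e-8)
        assert m.r2 == pytest.approx(sm_fit.rsquared, rel=1e-8)
        np.testing.assert_allclose(np.r_[m.intercept, m.coefficients], sm_fit.params,
                                   rtol=1e-8)
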