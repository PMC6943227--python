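"""Per-taxon presence/abundance models with OOB evaluation."""

import numpy as np
import pandas as pd
import pytest

import fmt_engraft as fe
from fmt_engraft.engraftment_prediction import _halving_grid

from .oracles import spearman_oracle


def _features(rng, n=80, p=8):
    X = pd.DataFrame(rng.random((n, p)), columns=[f"f{i}" for i in range(p)])
    prov = pd.Series(["donor_profile"] * p, index=X.columns)
    return fe.FeatureMatrix(X=X, provenance=prov)


class TestFilterRareTaxa:
    def _table(self, detected_counts, n_samples=15):
        rows = []
        for count in detected_counts:
            row = [0.01] * count + [0.0] * (n_samples - count)
            rows.append(row)
        df = pd.DataFrame(
            rows,
            index=[f"T{i}" for i in range(len(detected_counts))],
            columns=[f"S{i}" for i in range(n_samples)],
        )
        return fe.AbundanceTable(df)

    def test_boundary(self):
        out = fe.filter_rare_taxa(self._table([2, 3, 15]))
        assert out.taxon_ids == ["T1", "T2"]

    def test_ubiquitous_unchanged(self):
        table = self._table([15, 15])
        assert fe.filter_rare_taxa(table).taxon_ids == table.taxon_ids

    def test_detection_gate_is_applied(self):
        df = pd.DataFrame(
            [[0.0009] * 15, [0.0011] * 15], index=["lo", "hi"], columns=[f"S{i}" for i in range(15)]
        )
        out = fe.filter_rare_taxa(fe.AbundanceTable(df))
        assert out.taxon_ids == ["hi"]


class TestSelectMtry:
    def test_halving_grid(self):
        assert _halving_grid(13) == [13, 6, 3, 1]

    def test_single_feature_shortcut(self, rng):
        X = rng.random((20, 1))
        y = (X[:, 0] > 0.5).astype(int)
        assert fe.select_mtry(X, y, "presence") == 1

    def test_deterministic_given_seed(self, rng):
        X = rng.random((30, 16))
        y = rng.integers(0, 2, 30)
        a = fe.select_mtry(X, y, "presence", seed=42)
        b = fe.select_mtry(X, y, "presence", seed=42)
        assert a == b
        assert a in _halving_grid(16)

    def test_single_class_rejected(self, rng):
        X = rng.random((20, 4))
        with pytest.raises(fe.DegenerateTargetError):
            fe.select_mtry(X, np.zeros(20), "presence")


class TestPresenceModel:
    def test_copied_feature_is_perfectly_separable(self, rng):
        feats = _features(rng)
        feats.X["f0"] = rng.integers(0, 2, len(feats.X)).astype(float)
        y = feats.X["f0"].astype(int)  # target is a verbatim feature copy
        res = fe.fit_presence_model(feats, y, taxon_id="t", n_trees=150, seed=1)
        assert res.auc == pytest.approx(1.0)

    def test_single_class_target_skipped(self, rng):
        feats = _features(rng)
        with pytest.raises(fe.DegenerateTargetError):
            fe.fit_presence_model(feats, np.ones(len(feats.X)), n_trees=10)

    def test_determinism(self, rng):
        feats = _features(rng)
        y = (feats.X["f0"] + 0.2 * rng.random(len(feats.X)) > 0.6).astype(int)
        r1 = fe.fit_presence_model(feats, y, n_trees=60, seed=9, compute_importance=True)
        r2 = fe.fit_presence_model(feats, y, n_trees=60, seed=9, compute_importance=True)
        assert r1.auc == r2.auc
        assert np.array_equal(r1.importance.to_numpy(), r2.importance.to_numpy())

    def test_antipredictor_auc_is_complement(self, rng):
        """Training on flipped labels mirrors every tree (impurity is class-
        symmetric), so its scores rank the *original* labels in reverse."""
        from sklearn.metrics import roc_auc_score

        feats = _features(rng)
        y = (feats.X["f1"] + 0.3 * rng.random(len(feats.X)) > 0.7).astype(int).to_numpy()
        res = fe.fit_presence_model(feats, y, n_trees=80, seed=4)
        anti = fe.fit_presence_model(feats, 1 - y, n_trees=80, seed=4)
        valid = ~np.isnan(anti.oob_predictions)
        auc_vs_original = roc_auc_score(y[valid], anti.oob_predictions[valid])
        assert auc_vs_original == pytest.approx(1.0 - res.auc, abs=1e-9)

    def test_importance_finds_planted_feature(self, rng):
        feats = _features(rng, n=100)
        y = (feats.X["f3"] > 0.5).astype(int)
        res = fe.fit_presence_model(feats, y, n_trees=150, seed=2, compute_importance=True)
        assert res.importance.idxmax() == "f3"


class TestAbundanceModel:
    def test_self_predictable_target(self, rng):
        feats = _features(rng, n=200)
        y = feats.X["f0"].to_numpy()
        res = fe.fit_abundance_model(feats, y, n_trees=150, seed=3)
        valid = ~np.isnan(res.oob_predictions)
        rho, _ = spearman_oracle(list(res.oob_predictions[valid]), list(y[valid]))
        assert rho >= 0.9

    def test_constant_target_skipped(self, rng):
        feats = _features(rng)
        with pytest.raises(fe.DegenerateTargetError):
            fe.fit_abundance_model(feats, np.full(len(feats.X), 0.5), n_trees=10)


class TestPooling:
    def _result(self, preds, obs):
        return fe.PerTaxonModelResult(
            taxon_id="t",
            task="abundance",
            auc=None,
            oob_error=0.0,
            chosen_mtry=1,
            importance=None,
            n_positive=len(preds),
            oob_predictions=np.asarray(preds, dtype=float),
            observed=np.asarray(obs, dtype=float),
        )

    def test_identical_gives_rho_one(self):
        obs = [0.1, 0.2, 0.3, 0.4, 0.5]
        rho, p = fe.pool_regression_performance([self._result(obs, obs)])
        assert rho == pytest.approx(1.0)

    def test_reversed_gives_rho_minus_one(self):
        obs = [0.1, 0.2, 0.3, 0.4, 0.5]
        rho, _ = fe.pool_regression_performance([self._result(obs[::-1], obs)])
        assert rho == pytest.approx(-1.0)

    def test_matches_rank_oracle_on_hand_pairs(self):
        preds = [0.3, 0.1, 0.25, 0.9, 0.5, 0.05, 0.6, 0.2, 0.8, 0.4]
        obs = [0.2, 0.15, 0.3, 0.7, 0.55, 0.1, 0.5, 0.35, 0.6, 0.45]
        rho, p = fe.pool_regression_performance([self._result(preds, obs)])
        rho0, p0 = spearman_oracle(preds, obs)
        assert rho == pytest.approx(rho0, abs=1e-12)
        assert p == pytest.approx(p0, abs=1e-9)

    def test_empty_is_missing(self):
        assert fe.pool_regression_performance([]) == (None, None)


class TestAggregateImportance:
    def _result(self, importances, auc):
        return fe.PerTaxonModelResult(
            taxon_id="t",
            task="presence",
            auc=auc,
            oob_error=0.1,
            chosen_mtry=2,
            importance=pd.Series(importances),
            n_positive=5,
        )

    def test_single_qualifying_model_keeps_its_ranking(self):
        res = self._result({"a": 0.01, "b": 0.5, "c": 0.2}, auc=0.95)
        prov = pd.Series({"a": "donor_profile", "b": "recipient_clinical", "c": "donor_profile"})
        out = fe.aggregate_importance([res], prov, auc_min=0.9, top_k=2)
        assert list(out.feature) == ["b", "c"]
        assert out.iloc[0]["provenance"] == "recipient_clinical"

    def test_no_qualifying_model_is_empty(self):
        res = self._result({"a": 0.5}, auc=0.6)
        out = fe.aggregate_importance([res], pd.Series({"a": "donor_profile"}))
        assert out.empty

    def test_planted_feature_ranks_first_across_models(self):
        results = [
            self._result({"clin": 0.9, "x": 0.1, "y": 0.0}, 0.95),
            self._result({"clin": 0.7, "x": 0.0, "y": 0.2}, 0.97),
            self._result({"clin": 0.8, "x": 0.05, "y": 0.1}, 0.93),
        ]
        prov = pd.Series({"clin": "recipient_clinical", "x": "donor_profile", "y": "donor_profile"})
        out = fe.aggregate_importance(results, prov)
        assert out.iloc[0]["feature"] == "clin"


class TestCohortDriver:
    def test_or_rule_cohort_is_predictable(self):
        """Post-FMT presence that truly is 'in donor OR in baseline' is
        learnable from the donor/pre profiles."""
        spec = fe.CohortSimSpec(n_pairs=60, n_taxa=12, env_gain=0.0, timepoints=(3,), seed=19)
        abundance, manifest, _ = fe.simulate_species_cohort(spec)
        feats, post, recips = fe.build_feature_matrix(abundance, manifest)
        taxon = abundance.taxon_ids[0]
        donor_det = feats.X[f"donor:{taxon}"] >= 0.001
        pre_det = feats.X[f"pre:{taxon}"] >= 0.001
        y = (donor_det | pre_det).astype(int)
        if y.nunique() < 2:
            pytest.skip("degenerate draw")
        res = fe.fit_presence_model(feats, y, n_trees=200, seed=11)
        assert res.auc >= 0.9

    def test_predict_cohort_reports_sections(self, small_cohort):
        abundance, manifest, _ = small_cohort
        out = fe.predict_cohort(
            abundance, manifest, n_trees=30, select_mtry_cv=False, seed=2, compute_importance=False
        )
        assert out["n_presence_models"] > 0
        assert out["small_sample"] is True
        assert 0.0 <= out["mean_auc"] <= 1.0
        assert all(r.task in ("presence", "abundance") for r in out["results"])
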