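"""Linear SVM training, the scoring contract, routing and serialization."""

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone
from sklearn.svm import LinearSVC

from hotspots._topology import MUTABLE_AA
from hotspots.energetics import FEATURE_NAMES
from hotspots.evaluation import ClassificationCounts, precision_recall_f1
from hotspots.features import standardize
from hotspots.models import (
    HotspotEnsemble,
    HotspotEnsembleClassifier,
    LinearHotspotSVM,
    LinearModel,
    classify,
    predict_complex,
    train_linear_svm,
)
from hotspots.synthetic import SyntheticFeatureSpec, generate_feature_dataset


def scaled_dataset(n=200, noise=0.0, seed=0):
    data = generate_feature_dataset(SyntheticFeatureSpec(
        n_rows=n, label_noise=noise, seed=seed))
    scaled, stats = standardize(data.table)
    return data, scaled, stats


class TestTrainLinearSVM:
    def test_separable_data_reaches_perfect_training_f1(self):
        data, scaled, stats = scaled_dataset(n=100, noise=0.0, seed=11)
        model = train_linear_svm(scaled, FEATURE_NAMES, C=100.0, stats=stats)
        pred = np.where(model.decision_values(scaled, standardized=True) > 0, 1, -1)
        # ddG noise blurs labels near the threshold; allow the margin the
        # noise creates but demand near-perfect separation
        counts = ClassificationCounts.from_labels(scaled["label"], pred)
        assert precision_recall_f1(counts)[2] > 0.95

    def test_flipped_labels_negate_the_weights(self):
        data, scaled, stats = scaled_dataset(n=200, seed=12)
        m1 = train_linear_svm(scaled, FEATURE_NAMES, C=1.0)
        flipped = scaled.copy()
        flipped["label"] = -flipped["label"]
        m2 = train_linear_svm(flipped, FEATURE_NAMES, C=1.0)
        cos = (m1.weights @ m2.weights) / (
            np.linalg.norm(m1.weights) * np.linalg.norm(m2.weights))
        assert cos <= -0.99

    def test_recovers_planted_weights(self):
        data, scaled, stats = scaled_dataset(n=500, noise=0.05, seed=13)
        model = train_linear_svm(scaled, FEATURE_NAMES, C=1.0, class_weight=1.0)
        w_true = data.truth["weights"]
        cos = (model.weights @ w_true) / (
            np.linalg.norm(model.weights) * np.linalg.norm(w_true))
        assert cos > 0.9

    def test_single_class_is_hard_error(self):
        _, scaled, _ = scaled_dataset(n=50, seed=14)
        scaled["label"] = 1
        with pytest.raises(ValueError, match="single class"):
            train_linear_svm(scaled, FEATURE_NAMES)

    def test_non_finite_feature_is_hard_error(self):
        _, scaled, _ = scaled_dataset(n=50, seed=15)
        scaled.loc[scaled.index[0], "vdw_sc_inter"] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            train_linear_svm(scaled, FEATURE_NAMES)


class TestScoringContract:
    def test_score_matches_dot_product_oracle(self, rng):
        feats = FEATURE_NAMES[:5]
        for _ in range(20):
            w = rng.normal(size=5)
            b = rng.normal()
            model = LinearModel(feats, w, b)
            x = pd.Series(rng.normal(size=5), index=list(feats))
            assert model.score(x) == pytest.approx(
                float(np.dot(w, x.to_numpy()) - b), abs=1e-12)

    def test_score_is_linear_in_each_component(self, rng):
        model = LinearModel(FEATURE_NAMES[:3], np.array([0.5, -1.0, 2.0]), 0.3)
        x = pd.Series([1.0, 2.0, 3.0], index=list(FEATURE_NAMES[:3]))
        s0 = model.score(x)
        x2 = x.copy()
        x2.iloc[1] += 1.5
        assert model.score(x2) - s0 == pytest.approx(-1.0 * 1.5, abs=1e-12)

    def test_missing_component_is_hard_error(self):
        model = LinearModel(("vdw_sc_inter",), np.array([1.0]), 0.0)
        with pytest.raises(KeyError, match="missing component"):
            model.score(pd.Series({"hbond_sc_inter": 1.0}))

    def test_classify_flips_strictly_at_zero(self):
        assert classify(0.0) == -1
        assert classify(1e-9) == 1
        assert classify(-3.2) == -1

    def test_serialized_weight_table_rescores_backend_decisions(self):
        data, scaled, stats = scaled_dataset(n=150, seed=16)
        model = train_linear_svm(scaled, FEATURE_NAMES, C=1.0,
                                 class_weight=2.0, stats=stats)
        # independent backend reference on the same standardized matrix
        svc = LinearSVC(C=1.0, loss="hinge", class_weight={1: 2.0, -1: 1.0},
                        tol=1e-5, max_iter=50000, random_state=0)
        svc.fit(scaled[list(FEATURE_NAMES)].to_numpy(), scaled["label"])
        backend = svc.decision_function(scaled[list(FEATURE_NAMES)].to_numpy())
        reloaded = LinearModel.from_text(model.to_text())
        rescored = reloaded.decision_values(data.table)  # raw features in
        np.testing.assert_allclose(rescored, backend, atol=1e-6)


class TestRouting:
    @pytest.fixture()
    def ensemble(self):
        feats = FEATURE_NAMES[:2]
        return HotspotEnsemble(
            general=LinearModel(feats, np.array([1.0, 0.0]), 0.0),
            arg=LinearModel(feats, np.array([0.0, 1.0]), 0.0),
            glu=LinearModel(feats, np.array([-1.0, 0.0]), 0.0),
        )

    def test_routing_is_total_over_mutable_codes(self, ensemble):
        routed = {aa: ensemble.route(aa) for aa in MUTABLE_AA}
        assert routed["R"] is ensemble.arg
        assert routed["E"] is ensemble.glu
        general = [aa for aa, m in routed.items() if m is ensemble.general]
        assert len(general) == 15 and len(MUTABLE_AA) == 17

    @pytest.mark.parametrize("aa", ["A", "G", "P", "X"])
    def test_non_candidates_are_hard_errors(self, ensemble, aa):
        with pytest.raises(ValueError):
            ensemble.route(aa)

    def test_save_load_round_trip(self, ensemble, tmp_path):
        ensemble.save(tmp_path / "bundle")
        back = HotspotEnsemble.load(tmp_path / "bundle")
        x = pd.Series({FEATURE_NAMES[0]: 1.3, FEATURE_NAMES[1]: -0.7})
        for aa in ("W", "R", "E"):
            assert back.route(aa).score(x) == pytest.approx(
                ensemble.route(aa).score(x), abs=1e-12)


class TestPredictComplex:
    def test_one_row_per_interface_residue(self, toy_complex):
        from hotspots.structure import find_interface_residues

        feats = FEATURE_NAMES[:3]
        model = LinearModel(feats, np.array([-1.0, 0.0, -0.5]), 0.0)
        ens = HotspotEnsemble(model, model, model)
        table = predict_complex(ens, toy_complex)
        assert len(table) == len(find_interface_residues(toy_complex))
        assert list(table.columns) == ["chain", "resnum", "wt_aa", "score",
                                       "hotspot_call"]
        assert ((table["hotspot_call"] == 1) == (table["score"] > 0)).all()

    def test_no_interface_gives_empty_table(self):
        from hotspots.structure import read_complex
        from hotspots.synthetic import ToyComplexSpec, generate_toy_complex

        pdb_text, _ = generate_toy_complex(
            ToyComplexSpec(chains={"A": "NKSW", "B": "LNDY"}, separation=50.0))
        cx = read_complex(pdb_text, {"A"}, {"B"})
        model = LinearModel(FEATURE_NAMES[:1], np.array([1.0]), 0.0)
        assert len(predict_complex(HotspotEnsemble(model, model, model), cx)) == 0


class TestSklearnEstimators:
    def test_estimator_params_round_trip_and_clone(self):
        est = LinearHotspotSVM(C=10.0, class_weight=2.0)
        assert clone(est).get_params()["C"] == 10.0
        ens = HotspotEnsembleClassifier(C=0.5, glu_features=FEATURE_NAMES[:3])
        assert clone(ens).get_params()["glu_features"] == FEATURE_NAMES[:3]

    def test_fit_predict_exposes_weight_attributes(self):
        data = generate_feature_dataset(SyntheticFeatureSpec(n_rows=200, seed=17))
        est = LinearHotspotSVM(C=1.0).fit(
            data.table[list(FEATURE_NAMES)], data.table["label"])
        assert est.weights_.shape == (12,)
        pred = est.predict(data.table[list(FEATURE_NAMES)])
        assert set(pred) <= {-1, 1}
        assert (pred == np.where(
            est.decision_function(data.table[list(FEATURE_NAMES)]) > 0, 1, -1)).all()

    def test_ensemble_routes_rows_by_amino_acid(self):
        data = generate_feature_dataset(SyntheticFeatureSpec(n_rows=300, seed=18))
        X = data.table[["wt_aa"] + list(FEATURE_NAMES)]
        y = data.table["label"]
        est = HotspotEnsembleClassifier(
            glu_features=FEATURE_NAMES[:3], arg_features=FEATURE_NAMES[3:6]
        ).fit(X, y)
        s = est.decision_function(X)
        for aa, member in (("E", est.ensemble_.glu), ("R", est.ensemble_.arg)):
            mask = (X["wt_aa"] == aa).to_numpy()
            np.testing.assert_allclose(
                s[mask], member.decision_values(X.loc[mask]), atol=1e-12)
        rest = ~X["wt_aa"].isin(["R", "E"]).to_numpy()
        np.testing.assert_allclose(
            s[rest], est.ensemble_.general.decision_values(X.loc[rest]), atol=1e-12)
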