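"""Pseudoabsences, splits, ensemble assembly, map projection."""

import numpy as np
import pandas as pd
import pytest

from nicheshift import GridSpec
from nicheshift.ensemble import (
    EnsembleMember,
    EnsembleModel,
    EvaluationRecord,
    binarize,
    build_ensemble,
    predict_map,
    sample_pseudoabsences,
    split_train_test,
)
from nicheshift.errors import (
    ConfigurationError,
    EnsembleEmptyError,
    InsufficientDomainError,
    StratificationError,
)
from nicheshift.grid import EnvStack, RasterLayer
from nicheshift.models import FittedModel

from conftest import make_occ


def _stack(n_rows=5, n_cols=6, mask=None):
    spec = GridSpec(0, 0, 1.0, n_rows, n_cols)
    vals = np.arange(n_rows * n_cols, dtype=float).reshape(n_rows, n_cols)
    return EnvStack(spec, {"t": RasterLayer(spec, vals, mask, name="t")})


class TestPseudoabsences:
    def test_presence_cells_excluded_in_all_reps(self):
        stack = _stack()
        occ = make_occ([2.5], [2.5])  # one presence cell
        pres_cell = stack.spec.cell_of(2.5, 2.5)
        pas = sample_pseudoabsences(stack, occ, n=10, n_reps=3, seed=0)
        for pa in pas:
            cells = set(zip(pa.points["row"], pa.points["col"]))
            assert pres_cell not in cells
            assert len(cells) == 10  # without replacement

    def test_exactly_n_eligible_forces_full_coverage(self):
        stack = _stack(2, 3)
        occ = make_occ([0.5], [0.5])
        pas = sample_pseudoabsences(stack, occ, n=5, n_reps=2, seed=1)
        for pa in pas:
            assert len(set(zip(pa.points["row"], pa.points["col"]))) == 5

    def test_insufficient_domain_raises(self):
        stack = _stack(2, 4)
        occ = make_occ([0.5], [0.5])
        with pytest.raises(InsufficientDomainError):
            sample_pseudoabsences(stack, occ, n=10, n_reps=1, seed=0)

    def test_same_seed_reproducible(self):
        stack = _stack()
        occ = make_occ([2.5], [2.5])
        a = sample_pseudoabsences(stack, occ, n=8, n_reps=2, seed=3)
        b = sample_pseudoabsences(stack, occ, n=8, n_reps=2, seed=3)
        for pa, pb in zip(a, b):
            assert pa.points.equals(pb.points)


class TestSplits:
    def test_75_25_stratified_counts(self):
        labels = np.r_[np.ones(100), np.zeros(100)]
        folds = split_train_test(labels, seed=0)
        assert len(folds) == 6
        for tr, te in folds[:-1]:
            assert len(tr) == 150 and len(te) == 50
            assert labels[tr].sum() == 75
            assert labels[te].sum() == 25

    def test_partition_property(self):
        labels = np.r_[np.ones(40), np.zeros(60)]
        for tr, te in split_train_test(labels, seed=1)[:-1]:
            assert len(np.intersect1d(tr, te)) == 0
            assert len(np.union1d(tr, te)) == 100

    def test_final_pseudo_fold_uses_all_rows(self):
        labels = np.r_[np.ones(10), np.zeros(10)]
        tr, te = split_train_test(labels, seed=2)[-1]
        assert len(tr) == 20 and len(te) == 0

    def test_same_seed_identical(self):
        labels = np.r_[np.ones(30), np.zeros(30)]
        a = split_train_test(labels, seed=5)
        b = split_train_test(labels, seed=5)
        for (ta, ea), (tb, eb) in zip(a, b):
            np.testing.assert_array_equal(ta, tb)
            np.testing.assert_array_equal(ea, eb)

    def test_tiny_class_raises(self):
        with pytest.raises(StratificationError):
            split_train_test(np.r_[np.ones(3), np.zeros(50)], n_folds=5, seed=0)


def _member(tss, pred_value, alg="glm"):
    model = FittedModel(algorithm_id=alg, variables=["t"],
                        _impl=lambda X, v=pred_value: np.full(len(X), v))
    rec = EvaluationRecord(alg, 1, 1, tss, 0.9, 0.5)
    return EnsembleMember(model=model, record=rec)


def _eval_table(n=20):
    rng = np.random.default_rng(0)
    return pd.DataFrame({"t": rng.random(n),
                         "label": rng.integers(0, 2, n)})


class TestBuildEnsemble:
    def test_equal_tss_gives_equal_weights(self):
        ens = build_ensemble([_member(0.8, 0.2), _member(0.8, 0.8)],
                             _eval_table(), tss_min=0.75)
        np.testing.assert_allclose(ens.weights, [0.5, 0.5])

    def test_low_tss_member_filtered(self):
        ens = build_ensemble([_member(0.9, 0.2), _member(0.6, 0.8)],
                             _eval_table(), tss_min=0.75)
        assert len(ens.members) == 1
        np.testing.assert_allclose(ens.weights, [1.0])

    def test_weights_sum_to_one(self):
        ens = build_ensemble([_member(0.95, 0.1), _member(0.8, 0.5),
                              _member(0.77, 0.9)], _eval_table(), tss_min=0.75)
        assert ens.weights.sum() == pytest.approx(1.0)
        np.testing.assert_allclose(ens.weights,
                                   np.array([0.95, 0.8, 0.77]) / 2.52)

    def test_empty_ensemble_raises_with_report(self):
        with pytest.raises(EnsembleEmptyError) as exc:
            build_ensemble([_member(0.5, 0.2), _member(0.7, 0.8)],
                           _eval_table(), tss_min=0.75)
        assert len(exc.value.tss_report) == 2


class TestPredictMap:
    def test_constant_model_gives_constant_map(self):
        stack = _stack()
        model = FittedModel("glm", ["t"], _impl=lambda X: np.full(len(X), 0.4))
        out = predict_map(model, stack)
        np.testing.assert_allclose(out.values, 0.4)

    def test_singleton_ensemble_equals_member_map(self):
        stack = _stack()
        member = _member(0.9, 0.0)
        member.model._impl = lambda X: X["t"].to_numpy() / 100.0
        ens = EnsembleModel([member], np.array([1.0]), 0.75, 0.5, ["t"])
        np.testing.assert_allclose(predict_map(ens, stack).values,
                                   predict_map(member.model, stack).values)

    def test_equal_weight_pair_averages_member_maps(self):
        stack = _stack()
        m1 = _member(0.8, 0.0)
        m1.model._impl = lambda X: X["t"].to_numpy() / 100.0
        m2 = _member(0.8, 0.0)
        m2.model._impl = lambda X: np.full(len(X), 0.5)
        ens = EnsembleModel([m1, m2], np.array([0.5, 0.5]), 0.75, 0.5, ["t"])
        expected = (predict_map(m1.model, stack).values
                    + predict_map(m2.model, stack).values) / 2.0
        np.testing.assert_allclose(predict_map(ens, stack).values, expected)

    def test_nodata_propagates(self):
        mask = np.zeros((5, 6), dtype=bool)
        mask[0, 0] = True
        stack = _stack(mask=mask)
        model = FittedModel("glm", ["t"], _impl=lambda X: np.full(len(X), 0.4))
        out = predict_map(model, stack)
        assert np.isnan(out.values[0, 0]) and out.mask[0, 0]

    def test_missing_layer_errors(self):
        stack = _stack()
        model = FittedModel("glm", ["zz"], _impl=lambda X: np.zeros(len(X)))
        with pytest.raises(ConfigurationError):
            predict_map(model, stack)


class TestBinarize:
    def test_threshold_rules(self):
        spec = GridSpec(0, 0, 1.0, 1, 3)
        lyr = RasterLayer(spec, np.array([[0.2, 0.55, 0.9]]))
        out = binarize(lyr, 0.55)
        np.testing.assert_array_equal(out.values, [[0.0, 1.0, 1.0]])  # >= rule

    def test_threshold_below_all_values_gives_ones(self):
        spec = GridSpec(0, 0, 1.0, 1, 3)
        lyr = RasterLayer(spec, np.array([[0.2, 0.5, 0.9]]))
        np.testing.assert_array_equal(binarize(lyr, 0.1).values, 1.0)

    def test_threshold_outside_unit_interval_errors(self):
        lyr = RasterLayer(GridSpec(0, 0, 1.0, 1, 2), np.array([[0.1, 0.2]]))
        with pytest.raises(ConfigurationError):
            binarize(lyr, 1.5)
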