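"""Metrics against brute-force oracles, parameter counting, k-fold, training."""

import numpy as np
import pytest
from sklearn.metrics import cohen_kappa_score, roc_auc_score

from swarmnas import TDCN_PSO_NOTATION
from swarmnas.arch import Architecture, LayerSpec, parse_architecture
from swarmnas.evaluation import (
    InstantiationError,
    SurrogateEvaluator,
    TrainerSpec,
    TrainingEvaluator,
    accuracy_from_confusion,
    auc_ovr,
    cohen_kappa,
    confusion_matrix,
    count_parameters,
    instantiate_network,
    stratified_kfold,
    train_and_score,
)


# -- independent oracles ----------------------------------------------------


def auc_by_pair_counting(scores, labels, k):
    """Brute force: concordant pairs count 1, ties 0.5."""
    pos = [s for s, l in zip(scores, labels) if l == k]
    neg = [s for s, l in zip(scores, labels) if l != k]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def kappa_by_direct_po_pe(cm):
    cm = np.asarray(cm, dtype=float)
    t = cm.sum()
    po = np.trace(cm) / t
    pe = float((cm.sum(1) * cm.sum(0)).sum()) / t**2
    return (po - pe) / (1 - pe)


class TestAccuracy:
    def test_diagonal_is_one(self):
        assert accuracy_from_confusion(np.diag([3, 7, 2])) == 1.0

    def test_hand_value(self):
        assert accuracy_from_confusion([[50, 0], [10, 40]]) == pytest.approx(0.9)

    def test_zero_diagonal_is_zero(self):
        assert accuracy_from_confusion([[0, 5], [5, 0]]) == 0.0

    def test_empty_matrix_raises(self):
        with pytest.raises(ValueError):
            accuracy_from_confusion(np.zeros((3, 3)))


class TestAUC:
    def test_perfect_ordering(self):
        scores = np.array([[0.9, 0.1], [0.8, 0.2], [0.2, 0.8], [0.1, 0.9]])
        macro, _ = auc_ovr(scores, np.array([0, 0, 1, 1]))
        assert macro == 1.0

    def test_binary_hand_value(self):
        # positives (0.9, 0.3) vs negatives (0.8, 0.2): 3 of 4 pairs concordant
        scores = np.column_stack([1 - np.array([0.9, 0.8, 0.3, 0.2]),
                                  [0.9, 0.8, 0.3, 0.2]])
        _, per_class = auc_ovr(scores, np.array([1, 0, 1, 0]))
        assert per_class[1] == pytest.approx(0.75)

    def test_all_ties_give_half(self):
        scores = np.full((6, 2), 0.5)
        macro, _ = auc_ovr(scores, np.array([0, 1, 0, 1, 0, 1]))
        assert macro == pytest.approx(0.5)

    def test_absent_class_skipped_with_warning_and_nan(self):
        scores = np.random.default_rng(0).random((5, 3))
        with pytest.warns(UserWarning, match="class 2"):
            macro, per_class = auc_ovr(scores, np.array([0, 0, 1, 1, 0]))
        assert np.isnan(per_class[2]) and not np.isnan(macro)

    def test_no_scorable_class_raises(self):
        scores = np.random.default_rng(0).random((4, 2))
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError):
                auc_ovr(scores, np.array([0, 0, 0, 0]))

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(3)
        scores = rng.random((40, 3))
        labels = rng.integers(0, 3, 40)
        a1, _ = auc_ovr(scores, labels)
        a2, _ = auc_ovr(np.exp(5 * scores), labels)
        assert a1 == pytest.approx(a2, abs=1e-12)


class TestKappa:
    def test_diagonal_is_one(self):
        assert cohen_kappa(np.diag([4, 4, 4])) == pytest.approx(1.0)

    def test_hand_value(self):
        # po = 0.8, pe = 0.52 -> (0.8-0.52)/0.48
        assert cohen_kappa([[25, 5], [5, 15]]) == pytest.approx(0.58333333333, abs=1e-9)

    def test_marginal_independence_gives_zero(self):
        row = np.array([30.0, 70.0])
        col = np.array([40.0, 60.0])
        cm = np.outer(row, col) / 100.0
        assert cohen_kappa(cm) == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_single_cell_raises(self):
        with pytest.raises(ValueError):
            cohen_kappa([[10, 0], [0, 0]])

    def test_quadratic_weighting_matches_sklearn(self):
        rng = np.random.default_rng(7)
        y1 = rng.integers(0, 5, 300)
        y2 = np.where(rng.random(300) < 0.6, y1, rng.integers(0, 5, 300))
        cm = confusion_matrix(y1, y2, 5)
        assert cohen_kappa(cm, "quadratic") == pytest.approx(
            cohen_kappa_score(y1, y2, weights="quadratic"), abs=1e-12
        )


class TestMetricOracles:
    def test_auc_and_kappa_match_brute_force_on_random_instances(self):
        """Rank-statistic AUC and marginal kappa vs exhaustive oracles."""
        rng = np.random.default_rng(12345)
        for _ in range(1000):
            n, k = int(rng.integers(4, 12)), int(rng.integers(2, 4))
            labels = rng.integers(0, k, n)
            if len(np.unique(labels)) < 2:
                continue
            scores = np.round(rng.random((n, k)), 1)  # coarse grid forces ties
            import warnings as w

            with w.catch_warnings():
                w.simplefilter("ignore")
                _, per_class = auc_ovr(scores, labels)
            for cls in range(k):
                if np.isnan(per_class[cls]):
                    continue
                oracle = auc_by_pair_counting(scores[:, cls], labels, cls)
                assert per_class[cls] == pytest.approx(oracle, abs=1e-12)
            cm = confusion_matrix(labels, rng.integers(0, k, n), k)
            if np.trace(cm) != cm.sum():
                assert cohen_kappa(cm) == pytest.approx(
                    kappa_by_direct_po_pe(cm), abs=1e-12
                )

    def test_auc_cross_checked_against_sklearn(self):
        rng = np.random.default_rng(2)
        labels = rng.integers(0, 3, 120)
        scores = rng.random((120, 3))
        scores /= scores.sum(1, keepdims=True)
        macro, _ = auc_ovr(scores, labels)
        ref = roc_auc_score(labels, scores, multi_class="ovr", average="macro")
        assert macro == pytest.approx(ref, abs=1e-12)


class TestParameterCount:
    def test_hand_counted_small_network(self):
        arch = Architecture(
            (
                LayerSpec.make("C2D", filter_count=2, kernel_size=3),
                LayerSpec.make("F"),
                LayerSpec.make("DE", unit_count=3),
            ),
            (8, 8, 1),
        )
        # conv 3*3*1*2+2 = 20, dense 128*3+3 = 387
        assert count_parameters(arch) == 407

    def test_single_unit_dense(self):
        arch = Architecture(
            (LayerSpec.make("F"), LayerSpec.make("DE", unit_count=1)), (1, 1, 1)
        )
        assert count_parameters(arch) == 2

    def test_parameterless_layers_contribute_nothing(self):
        # nothing follows the pooling, so its zero contribution is isolated
        a = parse_architecture("C2D", input_shape=(16, 16, 3))
        b = parse_architecture("C2D | MP", input_shape=(16, 16, 3))
        c = parse_architecture("C2D | MP | AP | F", input_shape=(16, 16, 3))
        assert count_parameters(a) == count_parameters(b) == count_parameters(c)

    def test_batchnorm_counts_two_per_channel(self):
        a = parse_architecture("C2D | F | DE", input_shape=(8, 8, 3))
        b = parse_architecture("C2D | BN | F | DE", input_shape=(8, 8, 3))
        assert count_parameters(b) - count_parameters(a) == 2 * 32


class TestInstantiation:
    def test_printed_pso_architecture_instantiates_at_128(self):
        arch = parse_architecture(TDCN_PSO_NOTATION, input_shape=(128, 128, 3))
        net = instantiate_network(arch, (128, 128, 3), n_classes=5, seed=0)
        assert net.n_params() > count_parameters(arch) > 0

    def test_dense_on_image_input_raises(self):
        from swarmnas.arch import ConstraintSet

        bad = Architecture((LayerSpec.make("DE"),), (16, 16, 3))
        lax = ConstraintSet(min_dense=0, flatten_before_dense=False)
        with pytest.raises(InstantiationError, match="layer 0"):
            instantiate_network(bad, (16, 16, 3), rules=lax)

    def test_pooling_underflow_names_layer_index(self):
        arch = parse_architecture(
            "C2D | MP | MP | MP | MP | MP | F | DE", input_shape=(16, 16, 3)
        )
        with pytest.raises(InstantiationError, match="layer 5"):
            instantiate_network(arch, (16, 16, 3))

    def test_forward_shape_and_determinism(self):
        arch = parse_architecture("C2D | BN | MP | F | DE", input_shape=(16, 16, 3))
        x = np.random.default_rng(0).random((4, 16, 16, 3)).astype(np.float32)
        p1 = instantiate_network(arch, (16, 16, 3), seed=3).predict_proba(x)
        p2 = instantiate_network(arch, (16, 16, 3), seed=3).predict_proba(x)
        assert p1.shape == (4, 5)
        np.testing.assert_array_equal(p1, p2)


class TestStratifiedKFold:
    def test_exact_division_two_classes(self):
        labels = np.array([0] * 20 + [1] * 10)
        folds = stratified_kfold(labels, 10, rng_seed=0)
        for f in folds:
            assert (labels[f] == 0).sum() == 2 and (labels[f] == 1).sum() == 1

    def test_single_fold_is_everything(self):
        folds = stratified_kfold(np.array([0, 1, 0, 1]), 1)
        assert len(folds) == 1 and len(folds[0]) == 4

    def test_small_class_error_names_class(self):
        labels = np.array([0] * 50 + [7] * 5)
        with pytest.raises(ValueError, match="class 7"):
            stratified_kfold(labels, 10)

    def test_folds_partition_indices(self):
        labels = np.random.default_rng(0).integers(0, 3, 90)
        folds = stratified_kfold(labels, 5, rng_seed=1)
        all_idx = np.sort(np.concatenate(folds))
        np.testing.assert_array_equal(all_idx, np.arange(90))


@pytest.fixture(scope="module")
def tiny_data():
    from swarmnas.synth import easy_profile, generate_dataset

    ds = generate_dataset(easy_profile(120, 24, 0.02, seed=0))
    return ds.images, ds.labels


class TestTrainAndScore:
    def test_untrained_network_scores_near_chance(self, tiny_data):
        images, labels = tiny_data
        arch = parse_architecture("C2D | MP | F | DE", input_shape=(24, 24, 3))
        accs = []
        for seed in range(4):
            net = instantiate_network(arch, (24, 24, 3), 5, seed=seed)
            res, fit = train_and_score(
                net, images[:90], labels[:90], images[90:], labels[90:],
                TrainerSpec(epochs=0, rng_seed=seed),
            )
            accs.append(res.accuracy)
        assert abs(np.mean(accs) - 0.2) < 0.15

    def test_same_seed_gives_identical_result(self, tiny_data):
        images, labels = tiny_data
        arch = parse_architecture("C2D | MP | F | DE", input_shape=(24, 24, 3))
        out = []
        for _ in range(2):
            net = instantiate_network(arch, (24, 24, 3), 5, seed=11)
            out.append(
                train_and_score(
                    net, images[:90], labels[:90], images[90:], labels[90:],
                    TrainerSpec(epochs=2, rng_seed=11),
                )
            )
        assert out[0][0] == out[1][0] and out[0][1] == out[1][1]

    def test_single_class_split_rejected(self, tiny_data):
        images, labels = tiny_data
        arch = parse_architecture("F | DE", input_shape=(24, 24, 3))
        net = instantiate_network(arch, (24, 24, 3), 5)
        ones = np.zeros(10, dtype=int)
        with pytest.raises(ValueError):
            train_and_score(net, images[:10], ones, images[10:20], ones,
                            TrainerSpec(epochs=1))


class TestSurrogate:
    def test_pure_function_of_architecture(self):
        ev = SurrogateEvaluator(seed=5)
        arch = parse_architecture("C2D | MP | F | DE")
        assert ev(arch) == ev(arch)
        assert 0.0 <= ev(arch) <= 1.0

    def test_distinguishes_architectures(self):
        ev = SurrogateEvaluator(seed=5)
        a = parse_architecture("C2D | MP | F | DE")
        b = parse_architecture("C2D | C2D | MP | F | DE")
        assert ev(a) != ev(b)
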