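import numpy as np
import pytest

from elnm.evaluation import (ConsensusConfig, EvaluationResult, compute_acc,
                             compute_auc, fixed_sensitivity_threshold,
                             partial_roc_ratio, sample_background,
                             weighted_elitist_consensus, _roc_curve, _partial_auc)
from elnm.models import SuitabilityMap
from elnm.raster import Grid

from conftest import make_stack


def suit_map(values, group_id="g"):
    values = np.atleast_2d(np.asarray(values, float))
    g = Grid(*values.shape, 0.0, float(values.shape[0]), 1.0)
    return SuitabilityMap(group_id, g, values, np.zeros(values.shape, bool))


class TestAUC:
    def test_four_pair_example(self):
        assert compute_auc([0.9, 0.7], [0.8, 0.1]) == pytest.approx(0.75)

    def test_perfect_separation(self):
        assert compute_auc([0.9, 0.8], [0.2, 0.1]) == 1.0

    def test_exhaustive_pairwise_oracle(self, rng):
        for _ in range(10):
            p = rng.choice(np.linspace(0, 1, 11), size=int(rng.integers(2, 50)))
            b = rng.choice(np.linspace(0, 1, 11), size=int(rng.integers(2, 50)))
            wins = sum(1.0 if x > y else 0.5 if x == y else 0.0
                       for x in p for y in b)
            assert compute_auc(p, b) == pytest.approx(wins / (len(p) * len(b)))

    def test_null_distribution_near_half(self, rng):
        p = rng.normal(size=10_000)
        b = rng.normal(size=10_000)
        assert compute_auc(p, b) == pytest.approx(0.5, abs=0.02)

    def test_sklearn_cross_check(self, rng):
        from sklearn.metrics import roc_auc_score

        p = rng.uniform(0, 1, 200)
        b = rng.uniform(0, 0.8, 300)
        y = np.r_[np.ones(200), np.zeros(300)]
        assert compute_auc(p, b) == pytest.approx(
            roc_auc_score(y, np.r_[p, b]), abs=1e-12)


class TestACC:
    def test_confusion_matrix_example(self):
        assert compute_acc([0.9, 0.4], [0.2, 0.6], 0.5) == pytest.approx(0.5)

    def test_perfect_split(self):
        assert compute_acc([0.9, 0.8], [0.1, 0.2], 0.5) == 1.0

    def test_zero_threshold_predicts_all_present(self):
        assert compute_acc([0.5] * 3, [0.5] * 7, 0.0) == pytest.approx(0.3)


def proc_oracle(presence, background, e):
    """Independent trapezoid integration of the partial-AUC ratio for one
    presence sample (no bootstrap)."""
    thr = sorted(set(list(presence) + list(background)), reverse=True)
    pts = [(0.0, 0.0)]
    for t in thr:
        pts.append((np.mean(np.asarray(background) >= t),
                    np.mean(np.asarray(presence) >= t)))
    pts.append((1.0, 1.0))
    min_tpr = 1.0 - e
    kept = [(x, y) for x, y in pts if y >= min_tpr]
    first = pts.index(kept[0])
    if first > 0 and kept[0][1] > min_tpr:
        x0, y0 = pts[first - 1]
        x1, y1 = kept[0]
        xc = x0 + (min_tpr - y0) * (x1 - x0) / (y1 - y0) if y1 > y0 else x0
        kept = [(xc, min_tpr)] + kept
    area = 0.0
    for (x0, y0), (x1, y1) in zip(kept, kept[1:]):
        area += (x1 - x0) * (y0 + y1) / 2
    null = (1 - kept[0][0] ** 2) / 2
    return area / null


class TestPartialROC:
    def test_uninformative_scores_give_ratio_one(self, rng):
        p = rng.uniform(0, 1, 1000)
        b = rng.uniform(0, 1, 1000)
        r = partial_roc_ratio(p, b, omission_e=0.10, n_boot=200, seed=4)
        assert r == pytest.approx(1.0, abs=0.1)

    def test_perfect_scores_always_beat_null(self, rng):
        p = rng.uniform(0.8, 1.0, 50)
        b = rng.uniform(0.0, 0.5, 200)
        r = partial_roc_ratio(p, b, n_boot=50, seed=1)
        assert r > 1.0

    def test_tiny_example_matches_trapezoid_oracle(self):
        p = [0.9, 0.6, 0.4]
        b = [0.8, 0.5, 0.3, 0.2, 0.1]
        fpr, tpr = _roc_curve(np.array(p, float), np.array(b, float))
        model, null = _partial_auc(fpr, tpr, 0.9)
        assert model / null == pytest.approx(proc_oracle(p, b, 0.10), abs=1e-12)

    def test_fewer_than_two_presences_rejected(self):
        with pytest.raises(ValueError):
            partial_roc_ratio([0.5], [0.1, 0.2])


class TestBackground:
    def test_oversampling_errors(self, rng, grid10):
        stack = make_stack(grid10, {"x": rng.random(grid10.shape)})
        with pytest.raises(ValueError):
            sample_background(stack, 101, seed=0)

    def test_seed_reproducibility(self, rng, grid10):
        stack = make_stack(grid10, {"x": rng.random(grid10.shape)})
        a = sample_background(stack, 20, seed=9)
        b = sample_background(stack, 20, seed=9)
        assert np.array_equal(a, b)

    def test_excluded_cells_never_drawn_exhaustively(self, rng):
        g = Grid(5, 5, 0.0, 5.0, 1.0)
        stack = make_stack(g, {"x": rng.random((5, 5))})
        exclude = np.array([g.cell_center(r, c) for r, c in [(0, 0), (2, 2), (4, 4)]])
        pts = sample_background(stack, 22, seed=1, exclude=exclude)  # all remaining
        drawn = {g.index_of(lon, lat) for lon, lat in pts}
        assert len(drawn) == 22
        assert drawn.isdisjoint({(0, 0), (2, 2), (4, 4)})


def ev(model_id, auc, proc=1.0):
    return EvaluationResult(model_id, acc=0.5, auc=auc, proc_ratio=proc,
                            n_presence=10, n_background=100)


class TestConsensus:
    def test_identical_predictions_are_fixed_point(self):
        maps = [suit_map([[0.3, 0.7]]) for _ in range(4)]
        out = weighted_elitist_consensus(maps, [ev(f"m{i}", 0.5 + 0.1 * i)
                                                for i in range(4)],
                                         ConsensusConfig(top_k=3))
        assert np.allclose(out.values, maps[0].values)

    def test_score_proportional_weighted_mean(self):
        maps = [suit_map([[1.0]]), suit_map([[0.0]])]
        evals = [ev("good", 0.75), ev("bad", 0.25)]
        out = weighted_elitist_consensus(maps, evals, ConsensusConfig(top_k=2))
        assert out.values[0, 0] == pytest.approx(0.75)
        assert dict(out.provenance)["good"] == pytest.approx(0.75)

    def test_top_one_equals_best_model(self, rng):
        maps = [suit_map(rng.random((3, 3))) for _ in range(3)]
        evals = [ev("a", 0.6), ev("b", 0.9), ev("c", 0.7)]
        out = weighted_elitist_consensus(maps, evals, ConsensusConfig(top_k=1))
        assert np.allclose(out.values, maps[1].values)

    def test_tie_break_by_proc_then_id(self, rng):
        maps = [suit_map(rng.random((2, 2))) for _ in range(2)]
        evals = [ev("b", 0.8, proc=1.0), ev("a", 0.8, proc=1.5)]
        out = weighted_elitist_consensus(maps, evals, ConsensusConfig(top_k=1))
        assert np.allclose(out.values, maps[1].values)

    def test_clamps_excess_top_k_with_warning(self, rng):
        maps = [suit_map(rng.random((2, 2)))]
        with pytest.warns(UserWarning, match="clamping"):
            weighted_elitist_consensus(maps, [ev("a", 0.8)],
                                       ConsensusConfig(top_k=5))

    def test_convex_combination_bounds(self, rng):
        maps = [suit_map(rng.random((6, 6))) for _ in range(5)]
        evals = [ev(f"m{i}", rng.uniform(0.5, 1.0)) for i in range(5)]
        out = weighted_elitist_consensus(maps, evals, ConsensusConfig(top_k=3))
        stackv = np.stack([m.values for m in maps])
        assert np.all(out.values >= stackv.min(axis=0) - 1e-12)
        assert np.all(out.values <= stackv.max(axis=0) + 1e-12)


class TestFixedSensitivityThreshold:
    def test_order_statistic_example(self):
        scores = [0.2, 0.3, 0.4, 0.5, 0.6, 0.65, 0.7, 0.8, 0.9, 1.0]
        tau, thresholded = fixed_sensitivity_threshold(
            suit_map([scores]), scores, s=0.10)
        assert tau == pytest.approx(0.3)
        assert int((np.array(scores) < tau).sum()) == 1  # one occurrence omitted
        assert thresholded.values[0, 0] == 0.0
        assert thresholded.values[0, 1] == pytest.approx(0.3)
        assert thresholded.omission_threshold == pytest.approx(0.3)

    def test_zero_sensitivity_keeps_everything(self):
        scores = [0.4, 0.6, 0.9]
        tau, _ = fixed_sensitivity_threshold(suit_map([scores]), scores, s=1e-9)
        assert tau == pytest.approx(0.4)

    def test_equal_scores_omit_nothing(self):
        scores = [0.7] * 8
        tau, out = fixed_sensitivity_threshold(suit_map([scores]), scores, s=0.25)
        assert tau == pytest.approx(0.7)
        assert np.all(out.values == 0.7)

    @pytest.mark.parametrize("s", [0.05, 0.10, 0.25])
    def test_omission_never_exceeds_sensitivity(self, rng, s):
        for _ in range(100):
            n = int(rng.integers(5, 80))
            scores = rng.random(n)
            tau, _ = fixed_sensitivity_threshold(suit_map([scores]), scores, s=s)
            assert (scores < tau).mean() <= s + 1e-12
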