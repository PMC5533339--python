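import itertools
import math

import numpy as np
import pandas as pd
import pytest

from cotb import evaluation as ev
from cotb.config import Config
from cotb.model import FEATURE_COLUMNS


def make_ranking(proteins):
    """Ranking DataFrame from an ordered protein list (best first)."""
    n = len(proteins)
    return pd.DataFrame({
        "protein": proteins,
        "score": np.linspace(1.0, 0.0, n),
        "rank": np.arange(1, n + 1),
    })


def random_ranking(rng, n, prevalence=0.3):
    proteins = [f"p{i:04d}" for i in range(n)]
    rng.shuffle(proteins)
    essential = set(rng.choice(proteins, size=int(prevalence * n), replace=False))
    return make_ranking(proteins), essential


class TestTopK:
    def test_counts_and_precision(self):
        ranking = make_ranking(["a", "b", "c", "d"])
        counts = ev.top_k_counts(ranking, {"a", "c"}, [1, 2, 4])
        assert counts == [(1, 1), (2, 1), (4, 2)]

    def test_all_essential_is_perfect(self):
        ranking = make_ranking([f"p{i}" for i in range(10)])
        essential = {f"p{i}" for i in range(10)}
        assert all(tp == k for k, tp in ev.top_k_counts(ranking, essential, [1, 5, 10]))

    def test_k_beyond_ranking_errors(self):
        with pytest.raises(ValueError):
            ev.top_k_counts(make_ranking(["a"]), set(), [2])

    def test_random_ranking_matches_prevalence(self):
        """Precision at k of a random order concentrates on the prevalence."""
        rng = np.random.default_rng(99)
        precisions = []
        for _ in range(50):
            ranking, essential = random_ranking(rng, 200, prevalence=0.3)
            (_, tp), = ev.top_k_counts(ranking, essential, [50])
            precisions.append(tp / 50)
        # binomial standard error of the mean ~ 0.0092
        assert np.mean(precisions) == pytest.approx(0.3, abs=0.04)


class TestSixMeasures:
    def test_hand_arithmetic(self):
        # 500 proteins: top 100 holds 50 essentials, 50 more essentials below
        top = [f"e{i}" for i in range(50)] + [f"n{i}" for i in range(50)]
        rest = [f"e{i}" for i in range(50, 100)] + [f"n{i}" for i in range(50, 400)]
        ranking = make_ranking(top + rest)
        essential = {f"e{i}" for i in range(100)}
        m = ev.six_measures(ranking, essential, top_fraction=0.2)
        assert (m.counts.tp, m.counts.fp, m.counts.tn, m.counts.fn) == (50, 50, 350, 50)
        assert m.sn == pytest.approx(0.5)
        assert m.sp == pytest.approx(0.875)
        assert m.ppv == pytest.approx(0.5)
        assert m.npv == pytest.approx(0.875)
        assert m.f_measure == pytest.approx(0.5)
        assert m.acc == pytest.approx(0.8)
        assert not m.degenerate

    def test_perfect_ranking_at_matching_prevalence(self):
        essential = {f"e{i}" for i in range(20)}
        ranking = make_ranking(sorted(essential) + [f"n{i}" for i in range(80)])
        m = ev.six_measures(ranking, essential, top_fraction=0.2)
        assert (m.sn, m.sp, m.ppv, m.npv, m.f_measure, m.acc) == (1, 1, 1, 1, 1, 1)

    def test_degenerate_flag_without_essentials(self):
        m = ev.six_measures(make_ranking(["a", "b", "c", "d", "e"]), set(), 0.2)
        assert m.degenerate
        assert m.sn == 0.0

    def test_conservation_and_f_bounds_on_random_rankings(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            n = int(rng.integers(20, 200))
            ranking, essential = random_ranking(rng, n, prevalence=float(rng.uniform(0.1, 0.5)))
            m = ev.six_measures(ranking, essential, top_fraction=0.2)
            assert m.counts.total == n
            if not m.degenerate:
                assert min(m.sn, m.ppv) - 1e-12 <= m.f_measure <= max(m.sn, m.ppv) + 1e-12


class TestCurves:
    def test_perfect_ranking_pr_and_jackknife(self):
        essential = {f"e{i}" for i in range(5)}
        ranking = make_ranking(sorted(essential) + [f"n{i}" for i in range(5)])
        pr = ev.pr_curve(ranking, essential)
        assert (pr["precision"][pr["recall"] < 1.0] == 1.0).all()
        jk = ev.jackknife_curve(ranking, essential)
        assert jk["cumulative_tp"].tolist() == [min(n, 5) for n in range(1, 11)]

    def test_worst_ranking_jackknife(self):
        essential = {f"e{i}" for i in range(4)}
        ranking = make_ranking([f"n{i}" for i in range(6)] + sorted(essential))
        jk = ev.jackknife_curve(ranking, essential)
        assert jk["cumulative_tp"].tolist() == [max(0, n - 6) for n in range(1, 11)]

    def test_pr_without_essentials_errors(self):
        with pytest.raises(ValueError):
            ev.pr_curve(make_ranking(["a", "b"]), set())

    def test_jackknife_without_essentials_is_zero(self):
        jk = ev.jackknife_curve(make_ranking(["a", "b"]), set())
        assert (jk["cumulative_tp"] == 0).all()

    def test_curve_invariants_on_random_rankings(self):
        rng = np.random.default_rng(23)
        for _ in range(100):
            ranking, essential = random_ranking(rng, int(rng.integers(10, 100)))
            jk = ev.jackknife_curve(ranking, essential)
            steps = np.diff(jk["cumulative_tp"].to_numpy(), prepend=0)
            assert set(steps.tolist()) <= {0, 1}
            assert jk["cumulative_tp"].iloc[-1] == len(essential)
            pr = ev.pr_curve(ranking, essential)
            assert (np.diff(pr["recall"]) >= -1e-15).all()
            products = pr["precision"].to_numpy() * pr["n"].to_numpy()
            assert np.allclose(products, np.round(products))


class TestOverlap:
    def test_identical_disjoint_partial(self):
        a = [f"p{i}" for i in range(10)]
        assert ev.overlap_rate(a, list(a)) == 100.0
        assert ev.overlap_rate(a, [f"q{i}" for i in range(10)]) == 0.0
        b = a[:4] + [f"q{i}" for i in range(6)]
        assert ev.overlap_rate(a, b) == pytest.approx(40.0)

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        pool = [f"p{i}" for i in range(30)]
        a = list(rng.choice(pool, size=10, replace=False))
        b = list(rng.choice(pool, size=10, replace=False))
        assert ev.overlap_rate(a, b) == ev.overlap_rate(b, a)

    def test_unequal_or_empty_errors(self):
        with pytest.raises(ValueError):
            ev.overlap_rate(["a"], ["a", "b"])
        with pytest.raises(ValueError):
            ev.overlap_rate([], [])


def mann_whitney_auc(scores, labels):
    """Exhaustive pairwise comparison; ties count half."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum(1.0 if p > q else 0.5 if p == q else 0.0
               for p, q in itertools.product(pos, neg))
    return wins / (len(pos) * len(neg))


class TestCrossValidatedAUC:
    def separable(self, n=60, seed=0):
        rng = np.random.default_rng(seed)
        labels = np.array([1] * (n // 3) + [0] * (n - n // 3))
        x = rng.normal(size=(n, len(FEATURE_COLUMNS)))
        x[labels == 1] += 6.0
        frame = pd.DataFrame(x, columns=FEATURE_COLUMNS)
        frame.index = pd.Index([f"p{i}" for i in range(n)], name="protein")
        frame["label"] = labels
        return frame

    def test_perfectly_separable_reaches_one(self):
        auc = ev.cross_validated_auc(self.separable(), Config(rf_trees=50, rf_seed=1), folds=5)
        assert auc == pytest.approx(1.0, abs=1e-9)

    def test_deterministic_given_seed(self):
        frame = self.separable(seed=5)
        cfg = Config(rf_trees=50, rf_seed=9)
        assert ev.cross_validated_auc(frame, cfg, 5) == ev.cross_validated_auc(frame, cfg, 5)

    def test_permuted_labels_chance_level(self):
        frame = self.separable(n=120, seed=2)
        aucs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            shuffled = frame.copy()
            shuffled["label"] = rng.permutation(frame["label"].to_numpy())
            aucs.append(ev.cross_validated_auc(shuffled, Config(rf_trees=50, rf_seed=seed), 5))
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.05)

    def test_too_few_rows_errors(self):
        with pytest.raises(ValueError):
            ev.cross_validated_auc(self.separable(n=8), Config(rf_trees=10), folds=10)

    def test_auc_matches_mann_whitney_oracle(self):
        """sklearn's ROC area equals the exhaustive pair statistic on small data."""
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(31)
        for _ in range(25):
            n = int(rng.integers(10, 50))
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            scores = np.round(rng.random(n), 2)  # coarse grid forces ties
            assert roc_auc_score(labels, scores) == pytest.approx(
                mann_whitney_auc(scores, labels), abs=1e-12
            )

    def test_auc_rank_invariance(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(13)
        labels = rng.integers(0, 2, size=40)
        labels[0], labels[1] = 0, 1
        scores = rng.random(40)
        assert roc_auc_score(labels, scores) == pytest.approx(
            roc_auc_score(labels, np.exp(3 * scores)), abs=1e-12
        )
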