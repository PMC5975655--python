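import numpy as np
import pytest
from scipy.special import expit
from sklearn.linear_model import LogisticRegression

from sematyp.featurizer import TrainingExample, build_training_set, examples_to_matrix
from sematyp.semkg import build_graph
from sematyp.therapy_model import (
    NO_PATH_SCORE,
    TherapyModel,
    objective,
    objective_gradient,
    objective_value,
    predict_probability,
    rank_candidates,
    score_triple,
    train,
)
from sematyp.vocab import SemanticVocabulary

from conftest import preds_for_edge, random_graph_preds


def toy_examples(rng, n=60, d=6, theta=None):
    """Synthetic logistic data with a known weight vector."""
    if theta is None:
        theta = rng.normal(size=d)
    X = rng.poisson(2.0, size=(n, d)).astype(float)
    p = expit((X - X.mean(0)) @ theta)
    y = (rng.random(n) < p).astype(int)
    if y.min() == y.max():  # ensure both classes
        y[0] = 1 - y[0]
    return [
        TrainingExample(X[i], int(y[i]), "d", "t", "s", ("d", "t", "s"))
        for i in range(n)
    ], theta


def make_model(theta, max_len=4):
    return TherapyModel(np.asarray(theta, float), "l2", 1.0, max_len)


class TestPredictProbability:
    def test_zero_weights_give_half(self):
        m = make_model(np.zeros(5))
        assert predict_probability(m, np.arange(5)) == 0.5

    def test_monotone_saturation(self):
        m = make_model([1.0])
        probs = [predict_probability(m, np.array([z])) for z in (1, 10, 100, 800)]
        assert all(a < b or b == 1.0 for a, b in zip(probs, probs[1:]))
        assert probs[-1] == pytest.approx(1.0)
        # and no overflow warnings / nan at very large logits
        assert predict_probability(make_model([-1.0]), np.array([800.0])) == pytest.approx(0.0)

    def test_matches_scalar_loop(self):
        rng = np.random.default_rng(2)
        theta = rng.normal(size=20)
        x = rng.poisson(3, size=20).astype(float)
        z = sum(float(theta[i]) * float(x[i]) for i in range(20))
        m = make_model(theta)
        assert predict_probability(m, x) == pytest.approx(1 / (1 + np.exp(-z)), abs=1e-12)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            predict_probability(make_model(np.zeros(3)), np.zeros(4))


class TestObjective:
    def test_zero_theta_is_n_log_half(self):
        rng = np.random.default_rng(0)
        ex, _ = toy_examples(rng, n=17)
        m = make_model(np.zeros(6))
        assert objective(m, ex) == pytest.approx(17 * np.log(0.5))

    def test_zero_theta_penalty_free(self):
        rng = np.random.default_rng(1)
        ex, _ = toy_examples(rng, n=10)
        X, y = examples_to_matrix(ex)
        assert objective_value(np.zeros(6), X, y, "l2", 1.0) == objective_value(
            np.zeros(6), X, y, "l2", 0.0
        )

    def test_empty_examples_rejected(self):
        with pytest.raises(ValueError):
            objective(make_model(np.zeros(3)), [])

    def test_matches_term_by_term_sum(self):
        rng = np.random.default_rng(3)
        ex, _ = toy_examples(rng, n=25)
        X, y = examples_to_matrix(ex)
        theta = rng.normal(scale=0.3, size=6)
        acc = 0.0
        for i in range(25):
            p = 1 / (1 + np.exp(-float(X[i] @ theta)))
            acc += y[i] * np.log(p) + (1 - y[i]) * np.log(1 - p)
        lam = 0.7
        expected = acc - lam * float(theta @ theta)
        assert objective_value(theta, X, y, "l2", lam) == pytest.approx(expected, abs=1e-10)

    @pytest.mark.parametrize("reg_kind", ["l1", "l2"])
    def test_gradient_matches_central_differences(self, reg_kind):
        rng = np.random.default_rng(4)
        ex, _ = toy_examples(rng, n=40)
        X, y = examples_to_matrix(ex)
        h = 1e-6
        for _ in range(20):
            theta = rng.normal(scale=0.5, size=6)
            grad = objective_gradient(theta, X, y, reg_kind, 1.0)
            for j in range(6):
                e = np.zeros(6)
                e[j] = h
                num = (
                    objective_value(theta + e, X, y, reg_kind, 1.0)
                    - objective_value(theta - e, X, y, reg_kind, 1.0)
                ) / (2 * h)
                assert grad[j] == pytest.approx(num, rel=1e-5, abs=1e-7)


class TestTrain:
    def test_separated_data_stays_finite_and_directed(self):
        X = np.array([[0.0], [1.0], [2.0], [3.0]])
        y = [0, 0, 1, 1]
        ex = [TrainingExample(X[i], y[i], "d", "t", "s", ()) for i in range(4)]
        m = train(ex, reg_kind="l2", reg_strength=1.0)
        assert np.isfinite(m.theta).all()
        assert m.theta[0] > 0

    def test_single_class_rejected(self):
        ex = [TrainingExample(np.ones(2), 1, "d", "t", "s", ()) for _ in range(5)]
        with pytest.raises(ValueError):
            train(ex)

    @pytest.mark.parametrize("reg_kind", ["l1", "l2"])
    def test_returned_theta_beats_perturbations(self, reg_kind):
        rng = np.random.default_rng(5)
        ex, _ = toy_examples(rng, n=80)
        X, y = examples_to_matrix(ex)
        m = train(ex, reg_kind=reg_kind, reg_strength=1.0)
        base = objective_value(m.theta, X, y, reg_kind, 1.0)
        for _ in range(100):
            pert = m.theta + rng.normal(scale=0.1, size=m.theta.shape)
            assert base >= objective_value(pert, X, y, reg_kind, 1.0) - 1e-8

    def test_matches_sklearn_ridge_logistic(self):
        """Same objective as sklearn's L2 logistic regression with
        C = 1/(2*lambda) and no intercept."""
        rng = np.random.default_rng(6)
        ex, _ = toy_examples(rng, n=200, d=5)
        X, y = examples_to_matrix(ex)
        lam = 0.5
        mine = train(ex, reg_kind="l2", reg_strength=lam)
        sk = LogisticRegression(
            C=1.0 / (2 * lam), fit_intercept=False,
            solver="lbfgs", max_iter=5000, tol=1e-10,
        ).fit(X, y)
        np.testing.assert_allclose(mine.theta, sk.coef_.ravel(), atol=2e-4)

    def test_l1_shrinks_more_coordinates_to_zero(self):
        rng = np.random.default_rng(7)
        ex, _ = toy_examples(rng, n=150, d=8)
        l1 = train(ex, reg_kind="l1", reg_strength=5.0)
        l2 = train(ex, reg_kind="l2", reg_strength=5.0)
        assert np.sum(np.abs(l1.theta) < 1e-8) >= np.sum(np.abs(l2.theta) < 1e-8)

    def test_regularization_path_monotone(self):
        rng = np.random.default_rng(8)
        ex, _ = toy_examples(rng, n=120, d=6)
        norms = [
            np.linalg.norm(train(ex, reg_kind="l2", reg_strength=lam).theta)
            for lam in (0.0001, 0.01, 1.0, 100.0)
        ]
        assert all(a >= b - 1e-9 for a, b in zip(norms, norms[1:]))

    def test_serialization_round_trip(self, vocab, tmp_path):
        rng = np.random.default_rng(9)
        d = vocab.n_types * 5 + vocab.n_relations * 4
        m = TherapyModel(rng.normal(size=d), "l2", 1.0, 4, vocab=vocab,
                         n_iter=12, converged=True, objective_value=-1.5)
        path = tmp_path / "model.json"
        m.to_json(path)
        loaded = TherapyModel.from_json(path)
        np.testing.assert_array_equal(loaded.theta, m.theta)
        assert loaded.vocab.entity_types == vocab.entity_types
        assert loaded.reg_strength == 1.0 and loaded.max_len == 4


@pytest.fixture()
def scoring_setup(vocab):
    """Small graph, a trained-ish model with vocabulary attached."""
    rng = np.random.default_rng(10)
    preds = random_graph_preds(rng, 10, 22, vocab)
    g = build_graph(preds)
    d = vocab.n_types * 5 + vocab.n_relations * 4
    model = TherapyModel(rng.normal(scale=0.01, size=d), "l2", 1.0, 4, vocab=vocab)
    return g, model


class TestScoreTriple:
    def test_mean_of_path_probabilities(self, scoring_setup, vocab):
        from sematyp.featurizer import featurize_path
        from sematyp.pathfinder import enumerate_constrained_paths

        g, model = scoring_setup
        nodes = sorted(g.entities)
        found = None
        for d in nodes:
            for s in nodes:
                for t in nodes:
                    if len({d, s, t}) < 3:
                        continue
                    pset = enumerate_constrained_paths(g, d, s, t, 4)
                    if len(pset) >= 3:
                        found = (d, t, s, pset)
                        break
                if found:
                    break
            if found:
                break
        assert found
        d, t, s, pset = found
        score, n = score_triple(model, g, d, t, s)
        probs = [
            predict_probability(model, featurize_path(g, p, vocab, 4)) for p in pset
        ]
        assert n == len(pset)
        assert score == pytest.approx(float(np.mean(probs)), abs=1e-12)

    def test_no_path_sentinel(self, scoring_setup):
        g, model = scoring_setup
        nodes = sorted(g.entities)
        score, n = score_triple(model, g, nodes[0], "absent", nodes[1])
        assert (score, n) == (NO_PATH_SCORE, 0)


class TestRankCandidates:
    def test_unreachable_drug_sorts_last(self, vocab):
        preds = preds_for_edge("drugA", "phsu", "TREATS", "tgt", "horm", ["1", "2"])
        preds += preds_for_edge("tgt", "horm", "AFFECTS", "dis", "dsyn", ["3", "4"])
        preds += preds_for_edge("drugB", "phsu", "TREATS", "lonely", "horm", ["5", "6"])
        g = build_graph(preds)
        d = vocab.n_types * 5 + vocab.n_relations * 4
        model = TherapyModel(np.zeros(d), "l2", 1.0, 4, vocab=vocab)
        ranking = rank_candidates(model, g, "dis", ["drugA", "drugB"], ["tgt"])
        assert [r.drug for r in ranking] == ["drugA", "drugB"]
        assert ranking[0].score == pytest.approx(0.5)  # zero weights
        assert ranking[1].score == NO_PATH_SCORE
        assert ranking[0].rank == 1 and ranking[1].rank == 2

    def test_matches_exhaustive_score_triple(self, scoring_setup):
        g, model = scoring_setup
        nodes = sorted(g.entities)
        disease = nodes[0]
        drugs = nodes[1:7]
        targets = nodes[7:10]
        ranking = rank_candidates(model, g, disease, drugs, targets, aggregate="max")
        # brute force: per-drug max over targets of score_triple
        for r in ranking:
            scores = {}
            for t in targets:
                s, n = score_triple(model, g, r.drug, t, disease)
                scores[t] = (s, n)
            best = max(scores.items(), key=lambda kv: (kv[1][0], kv[0]))
            if best[1][1] == 0:
                assert r.score == NO_PATH_SCORE and r.best_target is None
            else:
                assert r.score == pytest.approx(best[1][0], abs=1e-9)
                assert r.best_target == best[0]
        # ordering is by descending score with id tie-break
        keys = [(-r.score, r.drug) for r in ranking]
        assert keys == sorted(keys)

    def test_pooled_score_averages_union_of_paths(self, scoring_setup):
        """The default drug score is the mean probability over the union
        of connecting paths through any candidate target, each path
        counted once."""
        from sematyp.featurizer import featurize_path
        from sematyp.pathfinder import enumerate_constrained_paths

        g, model = scoring_setup
        nodes = sorted(g.entities)
        disease, drugs, targets = nodes[0], nodes[1:5], nodes[5:9]
        ranking = rank_candidates(model, g, disease, drugs, targets)
        for r in ranking:
            pool = {}
            for t in targets:
                for p in enumerate_constrained_paths(g, r.drug, disease, t, 4):
                    pool.setdefault(
                        p.nodes,
                        predict_probability(
                            model, featurize_path(g, p, model.vocab, 4)
                        ),
                    )
            if not pool:
                assert r.score == NO_PATH_SCORE
            else:
                assert r.n_paths == len(pool)
                assert r.score == pytest.approx(float(np.mean(list(pool.values()))), abs=1e-9)

    def test_scores_export_tsv(self, scoring_setup):
        from sematyp.therapy_model import scores_to_tsv

        g, model = scoring_setup
        nodes = sorted(g.entities)
        results = rank_candidates(model, g, nodes[0], nodes[1:4], nodes[4:7])
        text = scores_to_tsv(results)
        lines = text.strip().splitlines()
        assert lines[0].split("\t") == [
            "disease", "drug", "best_target", "score", "n_paths", "rank"
        ]
        assert len(lines) == 1 + len(results)

    def test_order_invariance(self, scoring_setup):
        g, model = scoring_setup
        nodes = sorted(g.entities)
        disease, drugs, targets = nodes[0], nodes[1:6], nodes[6:9]
        a = rank_candidates(model, g, disease, drugs, targets)
        b = rank_candidates(model, g, disease, drugs[::-1], targets[::-1])
        assert [(r.drug, r.rank) for r in a] == [(r.drug, r.rank) for r in b]
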