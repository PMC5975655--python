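"""Regularized logistic model over semantic-type path features.

Each connecting path of a (drug, target, disease) triple is a training
instance; the model weights every feature position (a semantic type at an
entity slot, or a relation label at a relation slot) and predicts the
probability that a path supports a true therapy:

    p(y=1 | x; theta) = exp(theta^T x) / (1 + exp(theta^T x))

fitted by maximizing the penalized conditional log-likelihood

    O(theta) = sum_i [ y_i ln p_i + (1 - y_i) ln(1 - p_i) ] - lambda * P(theta)

with P the squared Euclidean norm (ridge) or the L1 norm (lasso).  There
is no intercept by default: an all-zero path vector must score 0.5.  A
candidate triple is scored by the mean predicted probability over its
connecting paths (score -1 when no path exists), and a candidate drug for
a disease by the maximum triple score over candidate targets.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path as FilePath
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit

from .featurizer import (
    TrainingExample,
    examples_to_matrix,
    feature_length,
    featurize_path,
)
from .pathfinder import (
    DEFAULT_MAX_PATHS,
    Path,
    enumerate_constrained_paths,
    extend_path,
)
from .semkg import KnowledgeGraph
from .vocab import SemanticVocabulary

__all__ = [
    "TherapyModel",
    "CandidateScore",
    "predict_probability",
    "objective",
    "objective_gradient",
    "train",
    "score_triple",
    "rank_candidates",
    "NO_PATH_SCORE",
]

NO_PATH_SCORE = -1.0


@dataclass
class TherapyModel:
    """Fitted weights plus the settings needed to score new triples."""

    theta: np.ndarray
    reg_kind: str  # "l1" or "l2"
    reg_strength: float
    max_len: int
    vocab: SemanticVocabulary | None = None
    n_iter: int = 0
    converged: bool = False
    objective_value: float = float("nan")
    with_intercept: bool = False
    intercept: float = 0.0

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=np.float64)
        if self.reg_kind not in ("l1", "l2"):
            raise ValueError(f"reg_kind must be 'l1' or 'l2', got {self.reg_kind!r}")
        if self.reg_strength < 0:
            raise ValueError("reg_strength must be nonnegative")
        if self.vocab is not None:
            expected = feature_length(self.vocab, self.max_len)
            if self.theta.shape != (expected,):
                raise ValueError(
                    f"theta length {self.theta.shape[0]} does not match "
                    f"K*(l+1)+M*l = {expected}"
                )

    # -- serialization ---------------------------------------------------

    def to_json(self, path: str | FilePath) -> None:
        payload = {
            "theta": self.theta.tolist(),
            "reg_kind": self.reg_kind,
            "reg_strength": self.reg_strength,
            "max_len": self.max_len,
            "with_intercept": self.with_intercept,
            "intercept": self.intercept,
            "n_iter": self.n_iter,
            "converged": self.converged,
            "objective_value": self.objective_value,
        }
        if self.vocab is not None:
            payload["vocab"] = {
                "entity_types": list(self.vocab.entity_types),
                "relation_types": list(self.vocab.relation_types),
                "sha256": _vocab_hash(self.vocab),
            }
        FilePath(path).write_text(json.dumps(payload), encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | FilePath) -> "TherapyModel":
        payload = json.loads(FilePath(path).read_text(encoding="utf-8"))
        vocab = None
        if "vocab" in payload:
            vocab = SemanticVocabulary(
                tuple(payload["vocab"]["entity_types"]),
                tuple(payload["vocab"]["relation_types"]),
            )
            if _vocab_hash(vocab) != payload["vocab"]["sha256"]:
                raise ValueError("vocabulary hash mismatch")
        return cls(
            theta=np.array(payload["theta"], dtype=np.float64),
            reg_kind=payload["reg_kind"],
            reg_strength=payload["reg_strength"],
            max_len=payload["max_len"],
            vocab=vocab,
            n_iter=payload["n_iter"],
            converged=payload["converged"],
            objective_value=payload["objective_value"],
            with_intercept=payload.get("with_intercept", False),
            intercept=payload.get("intercept", 0.0),
        )


def _vocab_hash(vocab: SemanticVocabulary) -> str:
    blob = "\x00".join(vocab.entity_types) + "\x01" + "\x00".join(vocab.relation_types)
    return hashlib.sha256(blob.encode("utf-8")).hexdigest()


# -- probability, objective, gradient ---------------------------------------


def predict_probability(model: TherapyModel, x: np.ndarray) -> float:
    """Logistic sigmoid of theta.x; numerically stable at extreme logits."""
    x = np.asarray(x, dtype=np.float64)
    if x.shape != model.theta.shape:
        raise ValueError(
            f"feature length {x.shape} does not match theta {model.theta.shape}"
        )
    return float(expit(model.theta @ x + model.intercept))


def _penalty(theta: np.ndarray, reg_kind: str) -> float:
    if reg_kind == "l2":
        return float(theta @ theta)
    return float(np.abs(theta).sum())


def _log_likelihood(theta: np.ndarray, X: np.ndarray, y: np.ndarray) -> float:
    z = X @ theta
    # y ln p + (1-y) ln(1-p) = y z - ln(1 + e^z), evaluated without overflow
    return float(y @ z - np.logaddexp(0.0, z).sum())


def objective(model: TherapyModel, examples: Sequence[TrainingExample]) -> float:
    """Penalized conditional log-likelihood of the examples under the model."""
    if len(examples) == 0:
        raise ValueError("objective requires at least one example")
    X, y = examples_to_matrix(examples)
    return objective_value(
        model.theta, X, y, model.reg_kind, model.reg_strength
    )


def objective_value(
    theta: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    reg_kind: str = "l2",
    reg_strength: float = 1.0,
) -> float:
    return _log_likelihood(theta, X, y) - reg_strength * _penalty(theta, reg_kind)


def objective_gradient(
    theta: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    reg_kind: str = "l2",
    reg_strength: float = 1.0,
) -> np.ndarray:
    """Analytic gradient of the penalized log-likelihood.

    d/dtheta [sum_i o_i] = X^T (y - p); the ridge penalty contributes
    -2*lambda*theta, the lasso penalty -lambda*sign(theta) (a subgradient,
    exact wherever no coordinate is zero).
    """
    p = expit(X @ theta)
    grad = X.T @ (y - p)
    if reg_kind == "l2":
        grad -= 2.0 * reg_strength * theta
    else:
        grad -= reg_strength * np.sign(theta)
    return grad


# -- training ----------------------------------------------------------------


def train(
    examples: Sequence[TrainingExample],
    reg_kind: str = "l2",
    reg_strength: float = 1.0,
    seed: int = 0,
    vocab: SemanticVocabulary | None = None,
    max_len: int | None = None,
    with_intercept: bool = False,
    gtol: float = 1e-6,
    max_iter: int = 2000,
) -> TherapyModel:
    """Maximize the penalized log-likelihood from a zero initialization.

    The ridge objective is smooth and concave and is maximized with
    L-BFGS; the lasso objective is maximized by FISTA (proximal gradient
    with momentum), whose soft-thresholding step handles the kink exactly.
    Both are deterministic; ``seed`` is accepted for interface uniformity
    but no randomness is used.
    """
    if len(examples) == 0:
        raise ValueError("no training examples")
    X, y = examples_to_matrix(examples)
    if y.min() == y.max():
        raise ValueError("training data contains a single class")
    if with_intercept:
        X = np.hstack([X, np.ones((X.shape[0], 1))])
    d = X.shape[1]
    theta0 = np.zeros(d)

    # exact reparametrization: optimize on column-rescaled features (raw
    # occurrence counts are badly conditioned) with the penalty mapped so
    # the optimum corresponds to the original objective
    scale = np.sqrt((X**2).mean(axis=0))
    scale[scale < 1e-12] = 1.0
    Xs = X / scale

    if reg_kind == "l2":
        pen = reg_strength / scale**2
        if with_intercept:
            pen[-1] = 0.0  # intercept unpenalized

        def neg_obj(t: np.ndarray) -> float:
            return -(_log_likelihood(t, Xs, y) - float((pen * t) @ t))

        def neg_grad(t: np.ndarray) -> np.ndarray:
            p = expit(Xs @ t)
            return -(Xs.T @ (y - p) - 2.0 * pen * t)

        def neg_hessp(t: np.ndarray, v: np.ndarray) -> np.ndarray:
            p = expit(Xs @ t)
            w = p * (1.0 - p)
            return Xs.T @ (w * (Xs @ v)) + 2.0 * pen * v

        res = minimize(
            neg_obj,
            theta0,
            jac=neg_grad,
            hessp=neg_hessp,
            method="trust-ncg",
            options={"gtol": gtol, "maxiter": max_iter},
        )
        theta_full = res.x / scale
        n_iter = int(res.nit)
        # trust-ncg can stall with "bad approximation" at the optimum;
        # judge convergence by the gradient norm, relative to the start
        gnorm0 = np.linalg.norm(neg_grad(theta0))
        gnorm = np.linalg.norm(neg_grad(res.x))
        converged = bool(res.success) or gnorm <= gtol * max(1.0, gnorm0)
    elif reg_kind == "l1":
        lam = reg_strength / scale
        if with_intercept:
            lam[-1] = 0.0
        theta_scaled, n_iter, converged = _fista_l1(
            Xs, y, lam, max_iter=max_iter, tol=gtol,
        )
        theta_full = theta_scaled / scale
    else:
        raise ValueError(f"reg_kind must be 'l1' or 'l2', got {reg_kind!r}")

    intercept = 0.0
    loglik = _log_likelihood(theta_full, X, y)
    if with_intercept:
        theta_full, intercept = theta_full[:-1], float(theta_full[-1])
    obj = loglik - reg_strength * _penalty(theta_full, reg_kind)
    return TherapyModel(
        theta=theta_full,
        reg_kind=reg_kind,
        reg_strength=reg_strength,
        max_len=max_len if max_len is not None else 0,
        vocab=vocab if max_len is not None else None,
        n_iter=n_iter,
        converged=converged,
        objective_value=obj,
        with_intercept=with_intercept,
        intercept=intercept,
    )


def _fista_l1(
    X: np.ndarray,
    y: np.ndarray,
    lam: np.ndarray | float,
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> tuple[np.ndarray, int, bool]:
    """Proximal gradient with Nesterov momentum for the lasso objective.

    Minimizes f(t) = -sum_i o_i(t) + |lam * t|_1 with a per-coordinate
    penalty vector.  The logistic negative log-likelihood has gradient
    Lipschitz constant at most ||X||_2^2 / 4.
    """
    n, d = X.shape
    lam = np.broadcast_to(np.asarray(lam, float), (d,))
    # spectral-norm bound via a few deterministic power iterations
    v = np.full(d, 1.0 / np.sqrt(d))
    for _ in range(30):
        w = X.T @ (X @ v)
        norm = np.linalg.norm(w)
        if norm == 0:
            break
        v = w / norm
    lipschitz = max(norm, 1e-12) / 4.0
    step = 1.0 / lipschitz

    theta = np.zeros(d)
    z = theta.copy()
    t_mom = 1.0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        p = expit(X @ z)
        grad = -(X.T @ (y - p))
        candidate = z - step * grad
        new_theta = np.sign(candidate) * np.maximum(
            np.abs(candidate) - step * lam, 0.0
        )
        t_next = (1.0 + np.sqrt(1.0 + 4.0 * t_mom**2)) / 2.0
        z = new_theta + ((t_mom - 1.0) / t_next) * (new_theta - theta)
        delta = np.max(np.abs(new_theta - theta))
        theta = new_theta
        t_mom = t_next
        if delta < tol:
            converged = True
            break
    return theta, it, converged


# -- scoring and ranking -----------------------------------------------------


def score_triple(
    model: TherapyModel,
    graph: KnowledgeGraph,
    drug: str,
    target: str,
    disease: str,
    max_paths: int | None = DEFAULT_MAX_PATHS,
) -> tuple[float, int]:
    """Mean predicted probability over all connecting paths of the triple.

    Returns (-1, 0) when no path of length 2..max_len through the target
    exists.
    """
    if model.vocab is None:
        raise ValueError("model carries no vocabulary; train with vocab and max_len")
    pset = enumerate_constrained_paths(
        graph, drug, disease, target, model.max_len, max_paths=max_paths
    )
    if len(pset) == 0:
        return NO_PATH_SCORE, 0
    probs = [
        predict_probability(
            model, featurize_path(graph, p, model.vocab, model.max_len)
        )
        for p in pset
    ]
    return float(np.mean(probs)), len(pset)


@dataclass
class CandidateScore:
    """Ranking record for one candidate drug against one disease."""

    drug: str
    disease: str
    best_target: str | None
    score: float
    n_paths: int
    per_target: Mapping[str, tuple[float, int]] = field(default_factory=dict)
    rank: int = 0


class _FastPathScorer:
    """Slot-wise cached logits: identical arithmetic to featurize+sigmoid,
    but reuses per-(slot, entity) and per-(slot, pair) dot products so that
    ranking sweeps over many candidate triples stay tractable."""

    def __init__(self, model: TherapyModel, graph: KnowledgeGraph) -> None:
        if model.vocab is None:
            raise ValueError("model carries no vocabulary")
        self.graph = graph
        self.vocab = model.vocab
        self.max_len = model.max_len
        self.intercept = model.intercept
        K, M = self.vocab.n_types, self.vocab.n_relations
        self.ent_segments = []
        self.rel_segments = []
        offset = 0
        for i in range(self.max_len + 1):
            self.ent_segments.append(model.theta[offset : offset + K])
            offset += K
            if i < self.max_len:
                self.rel_segments.append(model.theta[offset : offset + M])
                offset += M
        self._ent_cache: list[dict[str, float]] = [{} for _ in range(self.max_len + 1)]
        self._rel_cache: list[dict[tuple[str, str], float]] = [
            {} for _ in range(self.max_len)
        ]

    def _ent_dot(self, slot: int, entity: str) -> float:
        cache = self._ent_cache[slot]
        if entity not in cache:
            seg = self.ent_segments[slot]
            vocab = self.vocab
            cache[entity] = float(
                sum(
                    count * seg[vocab.type_index(label)]
                    for label, count in self.graph.type_counts[entity].items()
                )
            )
        return cache[entity]

    def _rel_dot(self, slot: int, a: str, b: str) -> float:
        key = (a, b) if a <= b else (b, a)
        cache = self._rel_cache[slot]
        if key not in cache:
            seg = self.rel_segments[slot]
            vocab = self.vocab
            cache[key] = float(
                sum(
                    count * seg[vocab.relation_index(label)]
                    for label, (count, _p) in self.graph.relations_between(a, b).items()
                )
            )
        return cache[key]

    def probability(self, path: Path) -> float:
        ext = extend_path(path, self.max_len)
        tp = path.target_position
        pre_a, pre_b = path.nodes[tp - 1], path.nodes[tp]
        logit = self.intercept
        for i, node in enumerate(ext.nodes):
            logit += self._ent_dot(i, node)
            if i < self.max_len:
                a, b = ext.nodes[i], ext.nodes[i + 1]
                if a == b:
                    a, b = pre_a, pre_b
                logit += self._rel_dot(i, a, b)
        return float(expit(logit))


def rank_candidates(
    model: TherapyModel,
    graph: KnowledgeGraph,
    disease: str,
    candidate_drugs: Sequence[str],
    candidate_targets: Sequence[str],
    max_paths: int | None = DEFAULT_MAX_PATHS,
    aggregate: str = "pooled",
) -> list[CandidateScore]:
    """Score every drug x target combination and rank drugs for the disease.

    With ``aggregate="pooled"`` (default) a drug's score is the mean
    predicted probability over all its connecting paths through *any*
    candidate target — the hypothetical-treatment pool a screening run
    evaluates when the disease's true target is unknown — and n_paths
    counts that pooled set (paths through two candidate targets counted
    once).  ``aggregate="max"`` instead scores the drug by its best
    single target.  Either way best_target records the arg-max per-target
    score, the putative mechanism.  Drugs with no connecting path through
    any target carry the sentinel score -1 and sort last.  Ties receive
    the worst (pessimistic) rank of their tie group; the listing order
    breaks ties by drug identifier.
    """
    if not candidate_drugs or not candidate_targets:
        raise ValueError("candidate lists must be nonempty")
    if aggregate not in ("pooled", "max", "mean"):
        raise ValueError("aggregate must be 'pooled', 'max' or 'mean'")
    from .pathfinder import _distances_within

    scorer = _FastPathScorer(model, graph)
    results: list[CandidateScore] = []
    targets = sorted(set(candidate_targets))
    max_len = model.max_len
    in_graph = disease in graph
    dist_s = _distances_within(graph, disease, max_len, False) if in_graph else {}
    dist_t_maps = {
        tgt: _distances_within(graph, tgt, max_len, False)
        for tgt in targets
        if tgt in graph and in_graph and dist_s.get(tgt, max_len + 1) < max_len
    }
    for drug in sorted(set(candidate_drugs)):
        per_target: dict[str, tuple[float, int]] = {}
        pooled: dict[tuple[str, ...], float] = {}
        for tgt in targets:
            dist_t = dist_t_maps.get(tgt)
            if (
                dist_t is None
                or drug == disease
                or drug not in graph
                or tgt in (drug, disease)
                or dist_t.get(drug, max_len + 1) + dist_s.get(tgt, max_len + 1)
                > max_len
            ):
                per_target[tgt] = (NO_PATH_SCORE, 0)
                continue
            pset = enumerate_constrained_paths(
                graph, drug, disease, tgt, max_len,
                max_paths=max_paths,
                _dist_to_target=dist_t, _dist_to_disease=dist_s,
            )
            if len(pset) == 0:
                per_target[tgt] = (NO_PATH_SCORE, 0)
                continue
            probs = [scorer.probability(p) for p in pset]
            per_target[tgt] = (float(np.mean(probs)), len(pset))
            for p, prob in zip(pset, probs):
                pooled.setdefault(p.nodes, prob)
        reachable = [(s, n, t) for t, (s, n) in per_target.items() if n > 0]
        if not reachable:
            results.append(
                CandidateScore(drug, disease, None, NO_PATH_SCORE, 0, per_target)
            )
        else:
            best = max(reachable, key=lambda r: (r[0], r[2]))
            if aggregate == "max":
                score, n_paths = best[0], best[1]
            elif aggregate == "mean":
                score = float(np.mean([s for s, _n, _t in reachable]))
                n_paths = sum(n for _s, n, _t in reachable)
            else:  # pooled: every connecting path counted once
                score = float(np.mean(list(pooled.values())))
                n_paths = len(pooled)
            results.append(
                CandidateScore(drug, disease, best[2], score, n_paths, per_target)
            )
    results.sort(key=lambda r: (-r.score, r.drug))
    scores = [r.score for r in results]
    for r in results:
        r.rank = sum(1 for s in scores if s >= r.score)  # pessimistic tie rank
    return results


def scores_to_tsv(results: Sequence[CandidateScore]) -> str:
    """Ranked candidate scores as TSV (disease, drug, best_target, score,
    n_paths, rank)."""
    lines = ["disease\tdrug\tbest_target\tscore\tn_paths\trank"]
    for r in results:
        lines.append(
            f"{r.disease}\t{r.drug}\t{r.best_target or '-'}"
            f"\t{r.score:.6g}\t{r.n_paths}\t{r.rank}"
        )
    return "\n".join(lines) + "\n"
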