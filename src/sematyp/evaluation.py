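"""Evaluation protocols: negative sampling, cross validation, rediscovery.

Negatives are built by corrupting gold (drug, target, disease) triples —
replacing one or more components with random pool members — and rejecting
any corruption that reproduces a gold triple.  Ten-fold cross validation
reports precision/recall/F over pooled test predictions.  The drug
rediscovery test hides a known therapy among decoy drugs, ranks all
candidates for the disease, and reports mean rank and hits@10; a known
drug with no connecting path gets the sentinel rank n_decoys + 2 (101 in
the canonical 99-decoy protocol).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path as FilePath
from typing import Callable, Sequence

import numpy as np

from .featurizer import TrainingExample, examples_to_matrix
from .pathfinder import enumerate_constrained_paths
from .semkg import KnowledgeGraph
from .therapy_model import NO_PATH_SCORE, train

__all__ = [
    "GoldTriple",
    "RediscoveryResult",
    "read_triples_tsv",
    "write_triples_tsv",
    "sample_negatives",
    "precision_recall_f",
    "cross_validate",
    "rediscovery_test",
    "regularization_grid",
]


@dataclass(frozen=True)
class GoldTriple:
    drug: str
    target: str
    disease: str
    label: bool = True

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.drug, self.target, self.disease)


@dataclass
class RediscoveryResult:
    """Aggregate outcome of the rediscovery protocol."""

    ranks: dict[tuple[str, str], int]  # (disease, known drug) -> rank
    mean_rank: float
    hits_at_10: float
    not_found: int
    n_candidates: int


def read_triples_tsv(path: str | FilePath) -> list[GoldTriple]:
    """Read drug/target/disease triples from a 3-column TSV ('#' comments)."""
    triples = []
    with open(path, encoding="utf-8") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].lstrip().startswith("#"):
                continue
            if len(row) < 3:
                raise ValueError(f"expected 3 columns, got {row!r}")
            triples.append(GoldTriple(row[0].strip(), row[1].strip(), row[2].strip()))
    return triples


def write_triples_tsv(path: str | FilePath, triples: Sequence[GoldTriple]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for t in triples:
            fh.write(f"{t.drug}\t{t.target}\t{t.disease}\n")


# -- negative sampling -------------------------------------------------------


def sample_negatives(
    positives: Sequence[GoldTriple],
    drug_pool: Sequence[str],
    target_pool: Sequence[str],
    disease_pool: Sequence[str],
    n: int,
    graph: KnowledgeGraph | None = None,
    seed: int = 0,
    max_len: int = 4,
    retry_cap: int = 100,
    replace: str = "all",
) -> list[GoldTriple]:
    """Corrupt gold triples into n negatives, reproducibly.

    With ``replace="all"`` (default) every draw replaces the drug, the
    target and the disease with uniform picks from the pools;
    ``replace="subset"`` instead replaces a random nonempty subset of
    components of a sampled positive.  A corruption is rejected if it
    equals any positive triple; when a graph is supplied it is also
    rejected unless at least one connecting path of length <= max_len
    exists (pathless triples yield no training rows).
    """
    if replace not in ("all", "subset"):
        raise ValueError("replace must be 'all' or 'subset'")
    if not (drug_pool and target_pool and disease_pool):
        raise ValueError("candidate pools must be nonempty")
    if not positives:
        raise ValueError("no positives to corrupt")
    rng = np.random.default_rng(seed)
    positive_keys = {p.key for p in positives}
    drug_pool = sorted(set(drug_pool))
    target_pool = sorted(set(target_pool))
    disease_pool = sorted(set(disease_pool))
    # multi-source BFS table from every candidate target: a triple can
    # only have a connecting path if dist(drug, t) + dist(t, disease)
    # fits the length budget, so infeasible corruptions reject in O(1)
    hop = None
    if graph is not None:
        from scipy.sparse.csgraph import dijkstra

        mat, _nodes, node_index = graph.csr_adjacency()
        sources = [t for t in target_pool if t in node_index]
        if sources:
            table = dijkstra(
                mat, directed=False, unweighted=True,
                indices=[node_index[t] for t in sources],
                limit=float(max_len - 1),
            )
            hop = ({t: i for i, t in enumerate(sources)}, node_index, table)
    negatives: list[GoldTriple] = []
    for i in range(n):
        base = positives[int(rng.integers(len(positives)))]
        for attempt in range(retry_cap):
            if replace == "all":
                mask = np.ones(3, dtype=int)
            else:
                # choose a nonempty subset of components to replace
                mask = rng.integers(0, 2, size=3)
                if not mask.any():
                    mask[int(rng.integers(3))] = 1
            drug = drug_pool[int(rng.integers(len(drug_pool)))] if mask[0] else base.drug
            target = (
                target_pool[int(rng.integers(len(target_pool)))]
                if mask[1]
                else base.target
            )
            disease = (
                disease_pool[int(rng.integers(len(disease_pool)))]
                if mask[2]
                else base.disease
            )
            key = (drug, target, disease)
            if key in positive_keys:
                continue
            if len({drug, target, disease}) < 3:
                continue
            if graph is not None:
                if hop is not None:
                    t_row, node_index, table = hop
                    if (
                        target not in t_row
                        or drug not in node_index
                        or disease not in node_index
                    ):
                        continue
                    row = table[t_row[target]]
                    if row[node_index[drug]] + row[node_index[disease]] > max_len:
                        continue
                pset = enumerate_constrained_paths(
                    graph, drug, disease, target, max_len, max_paths=1
                )
                if len(pset) == 0:
                    continue
            negatives.append(GoldTriple(drug, target, disease, label=False))
            break
        else:
            raise RuntimeError(
                f"negative sampling stalled after {retry_cap} retries; "
                f"achieved {len(negatives)} of {n}"
            )
    return negatives


# -- cross validation --------------------------------------------------------


def precision_recall_f(
    y_true: np.ndarray, y_pred: np.ndarray
) -> tuple[float, float, float]:
    """P = TP/(TP+FP), R = TP/(TP+FN), F = 2PR/(P+R); 0 where undefined."""
    y_true = np.asarray(y_true).astype(bool)
    y_pred = np.asarray(y_pred).astype(bool)
    tp = int(np.sum(y_true & y_pred))
    fp = int(np.sum(~y_true & y_pred))
    fn = int(np.sum(y_true & ~y_pred))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, f


def cross_validate(
    examples: Sequence[TrainingExample],
    folds: int = 10,
    reg_kind: str = "l2",
    reg_strength: float = 1.0,
    threshold: float = 0.5,
    seed: int = 0,
    with_intercept: bool = False,
) -> dict:
    """Random equal-size fold partition; per fold, train on the rest and
    classify the held-out fold at ``threshold``; metrics are pooled over
    all test predictions (per-fold values also reported)."""
    if folds < 2:
        raise ValueError("folds must be >= 2")
    X, y = examples_to_matrix(examples)
    if y.min() == y.max():
        raise ValueError("both classes must be present")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(examples))
    fold_of = np.empty(len(examples), dtype=int)
    fold_of[order] = np.arange(len(examples)) % folds
    pooled_true: list[np.ndarray] = []
    pooled_pred: list[np.ndarray] = []
    per_fold = []
    from scipy.special import expit

    for k in range(folds):
        test = fold_of == k
        train_idx = np.flatnonzero(~test)
        if y[train_idx].min() == y[train_idx].max():
            raise ValueError(f"training fold {k} contains a single class")
        model = train(
            [examples[i] for i in train_idx],
            reg_kind=reg_kind,
            reg_strength=reg_strength,
            with_intercept=with_intercept,
        )
        logits = X[test] @ model.theta + model.intercept
        pred = expit(logits) >= threshold
        p, r, f = precision_recall_f(y[test], pred)
        per_fold.append({"fold": k, "precision": p, "recall": r, "f_score": f})
        pooled_true.append(y[test])
        pooled_pred.append(pred)
    p, r, f = precision_recall_f(np.concatenate(pooled_true), np.concatenate(pooled_pred))
    return {
        "precision": p,
        "recall": r,
        "f_score": f,
        "folds": per_fold,
        "n_examples": len(examples),
    }


def regularization_grid(
    examples: Sequence[TrainingExample],
    lambdas: Sequence[float] = (0.0001, 0.001, 0.01, 0.1, 1.0, 10.0, 100.0),
    folds: int = 10,
    threshold: float = 0.5,
    seed: int = 0,
) -> list[dict]:
    """Lasso-vs-ridge comparison across a lambda grid.

    Returns one record per lambda with P/R/F for each penalty, the report
    shape used to choose the regularizer and its strength.
    """
    rows = []
    for lam in lambdas:
        row: dict = {"lambda": lam}
        for kind in ("l1", "l2"):
            res = cross_validate(
                examples,
                folds=folds,
                reg_kind=kind,
                reg_strength=lam,
                threshold=threshold,
                seed=seed,
            )
            row[f"precision_{kind}"] = res["precision"]
            row[f"recall_{kind}"] = res["recall"]
            row[f"f_score_{kind}"] = res["f_score"]
        rows.append(row)
    return rows


# -- drug rediscovery --------------------------------------------------------

Scorer = Callable[[KnowledgeGraph, str, str, Sequence[str]], float]


def rediscovery_test(
    scorer: Scorer,
    graph: KnowledgeGraph,
    pairs: Sequence[tuple[str, str]],
    decoy_pool: Sequence[str],
    n_decoys: int = 99,
    target_pool: Sequence[str] = (),
    seed: int = 0,
) -> RediscoveryResult:
    """Rank each disease's known drug among random decoys.

    ``scorer(graph, drug, disease, target_pool)`` returns a drug-level
    score, with -1 meaning the drug cannot be connected to the disease.
    A scorer exposing ``score_many(graph, drugs, disease, target_pool)``
    is called once per disease with the whole candidate list, which lets
    it share per-disease work.  Ranks use the pessimistic tie rule (a
    tied drug gets the worst rank of its tie group); an unconnected known
    drug is assigned rank n_decoys + 2 regardless of the decoys' scores.
    """
    if n_decoys < 1:
        raise ValueError("n_decoys must be >= 1")
    rng = np.random.default_rng(seed)
    ranks: dict[tuple[str, str], int] = {}
    not_found = 0
    batch = getattr(scorer, "score_many", None)
    for disease, known_drug in pairs:
        pool = sorted(set(decoy_pool) - {known_drug, disease})
        if len(pool) < n_decoys:
            raise ValueError(
                f"decoy pool has {len(pool)} drugs, need {n_decoys}"
            )
        decoys = list(rng.choice(pool, size=n_decoys, replace=False))
        if batch is not None:
            scores = batch(graph, [known_drug] + decoys, disease, target_pool)
            known_score = scores[known_drug]
            decoy_scores = [scores[d] for d in decoys]
        else:
            known_score = scorer(graph, known_drug, disease, target_pool)
            decoy_scores = None
        if known_score == NO_PATH_SCORE:
            rank = n_decoys + 2
            not_found += 1
        else:
            if decoy_scores is None:
                decoy_scores = [scorer(graph, d, disease, target_pool) for d in decoys]
            rank = 1 + sum(1 for s in decoy_scores if s >= known_score)
        ranks[(disease, known_drug)] = rank
    rank_values = np.array(list(ranks.values()), dtype=float)
    return RediscoveryResult(
        ranks=ranks,
        mean_rank=float(rank_values.mean()),
        hits_at_10=float(np.mean(rank_values <= 10)),
        not_found=not_found,
        n_candidates=n_decoys + 1,
    )


class make_model_scorer:
    """Adapter: drug-level scorer from a trained TherapyModel (max over
    candidate targets of the mean path probability).  Implements both the
    per-drug call and the per-disease batch interface; the batch path
    shares distance maps and feature caches across all candidates."""

    def __init__(self, model, aggregate: str = "max", max_paths=None) -> None:
        self.model = model
        self.aggregate = aggregate
        self.max_paths = max_paths

    def _kwargs(self):
        return {} if self.max_paths is None else {"max_paths": self.max_paths}

    def __call__(self, graph, drug, disease, target_pool):
        from .therapy_model import rank_candidates

        res = rank_candidates(
            self.model, graph, disease, [drug], list(target_pool),
            aggregate=self.aggregate, **self._kwargs(),
        )
        return res[0].score

    def score_many(self, graph, drugs, disease, target_pool):
        from .therapy_model import rank_candidates

        res = rank_candidates(
            self.model, graph, disease, list(drugs), list(target_pool),
            aggregate=self.aggregate, **self._kwargs(),
        )
        return {r.drug: r.score for r in res}
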