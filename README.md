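# sematyp

Knowledge-graph literature mining for drug discovery.

`sematyp` is for computational biologists who want to rank candidate
drugs for a disease from the biomedical literature rather than from
screening data. It consumes *predications* — subject–relation–object
assertions extracted from abstracts (e.g. `Hemofiltration |topp TREATS
Patients |podg`, with UMLS semantic-type abbreviations and the source
PubMed id) — builds a semantic knowledge graph from them, and learns
what the connecting paths of *true* drug–target–disease therapies look
like in terms of the semantic types and relations along them.

## The model

Predications whose (subject, relation, object) key was extracted only
once are filtered out as extraction noise. The survivors form an
undirected multigraph: entities carry per-type occurrence counts, node
pairs carry per-relation occurrence counts and pmid provenance.

A candidate therapy (drug, target, disease) is supported by the simple
paths `drug … target … disease` of length 2..ℓ (ℓ = 4) whose interior
contains the target. Each path is featurized by interleaving the entity
type-occurrence vector T_E (length K = 133) of every node with the
relation-occurrence vector T_R (length M = 52) of every adjacent pair;
shorter paths are padded to ℓ by repeating the target. The result is a
count vector of length K·(ℓ+1) + M·ℓ = 873. A logistic model

    p(y = 1 | x; θ) = exp(θᵀx) / (1 + exp(θᵀx))

is trained on the paths of gold therapy triples (label 1) and of
randomly corrupted triples (label 0) by maximizing the
L2- (or L1-) penalized conditional log-likelihood, λ = 1 by default. A
triple is scored by the mean predicted probability over its connecting
paths (−1 when no path exists), and a candidate drug for a disease by
pooling its paths across all hypothetical targets; the best single
target is reported as the putative mechanism of action. A uniform
random-walk baseline (score = probability of reaching the disease
within t steps) and the standard evaluation protocols — ten-fold cross
validation with precision/recall/F and the 99-decoy drug rediscovery
test with mean rank and hits@10 — are included.

Because the corpora this method targets (tens of millions of abstracts,
curated therapy databases) are not redistributable, the package ships a
synthetic generator that emulates their statistics — sparse Dirichlet
type profiles, preferential-attachment hubs, Zipf relation frequencies,
occurrence counts that exercise the filter — and plants therapy triples
whose connecting paths are enriched in a signature subset of types and
relations. See `docs/methods.md` for the full model and generator
description.

## Worked example

Generate a small synthetic corpus, build the graph, cross-validate the
therapy model, and run the rediscovery test:

```bash
sematyp synthgen --config demo_config.json --seed 11 --out demo/corpus
# wrote 28315 predications, 60 gold triples

sematyp build --predications demo/corpus/predications.tsv \
    --vocab demo/corpus/vocabulary.json --out demo/build
# graph: 343 entities, 8037 relation instances

sematyp cv --predications demo/corpus/predications.tsv \
    --triples demo/corpus/gold_triples.tsv \
    --vocab demo/corpus/vocabulary.json --folds 5 --seed 11 --out demo/cv
# precision=0.936 recall=0.958 f_score=0.947 -> demo/cv/cv_report.json

sematyp rediscover --predications demo/corpus/predications.tsv \
    --triples demo/corpus/gold_triples.tsv \
    --pairs demo/corpus/rediscovery_pairs.tsv \
    --vocab demo/corpus/vocabulary.json --decoys 50 --seed 11 --out demo/redisc
# mean_ranking=19.33 hits@10=50.00% -> demo/redisc/rediscovery_report.json
```

where `demo_config.json` shrinks the generator for a quick run:

```json
{"k": 133, "m": 52, "n_gold_triples": 60, "n_heldout": 6,
 "n_intermediates": 150, "n_background_predications": 4000,
 "role_background_degree": 8, "n_parallel": 2, "signature_strength": 5.0}
```

Reading the output: the cross-validation line says that path rows of
held-out gold triples are told apart from corrupted-triple rows with
precision 0.936 and recall 0.958 at the 0.5 threshold. The rediscovery
line says that when each held-out disease's known drug is hidden among
50 random decoys, it lands at mean rank 19.3 and half of the known
drugs make the top 10. The same protocol through the random-walk
baseline (`sematyp rwa ... --steps 1,3`) shows why path semantics
matter: a walk reaches the disease from the known drug with probability
0.007 in three steps, ranking it no better than decoys.

The library mirrors the CLI one-to-one — `synthgen.generate_benchmark`,
`featurizer.build_training_set`, `therapy_model.train`,
`therapy_model.rank_candidates`, `evaluation.cross_validate`,
`evaluation.rediscovery_test` — see the docstrings.

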