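# Methods

## The model

`sematyp` implements a literature-based drug-discovery pipeline over a
semantic knowledge graph. The input is a corpus of *predications* —
subject–relation–object assertions extracted from biomedical abstracts,
each annotated with UMLS-style semantic types (e.g. `phsu`, a
pharmacologic substance, `TREATS`, `dsyn`, a disease or syndrome) and the
PubMed id of the source abstract.

**Graph construction.** Predications whose (subject, relation, object)
key was extracted only once are discarded as probable extraction noise.
The survivors form an undirected multigraph: each entity accumulates a
per-semantic-type occurrence count (one per predication slot mentioning
it); each unordered node pair accumulates per-relation occurrence counts
and pmid sets. The weight of an edge is the total number of predications
between its endpoints.

**Path features.** A candidate therapy (drug, target, disease) is
supported by the simple paths `drug … target … disease` of length 2..ℓ
whose interior contains the target (ℓ = 4 by default; the direct
drug–target–disease route has length 2). A path is featurized by
interleaving, slot by slot, the entity's semantic-type occurrence vector
T_E (length K) with the node pair's relation occurrence vector T_R
(length M), giving a nonnegative integer vector of length
K·(ℓ+1) + M·ℓ — 873 for K = 133, M = 52, ℓ = 4. Shorter paths are padded
to ℓ by repeating the target node; the inserted relation slots copy the
relation slot immediately preceding the target. T_E counts are
graph-global (all retained predications mentioning the entity), not
restricted to the path's edges; T_R pools both stored directions of a
pair. Counts are raw — no scaling or log transform.

**Therapy model.** Each connecting path of a gold (positive) or
corrupted (negative) triple is one training row. A logistic model
p(y=1|x; θ) = σ(θᵀx) is fitted, without intercept, by maximizing the
penalized conditional log-likelihood Σᵢ[yᵢ ln pᵢ + (1−yᵢ) ln(1−pᵢ)] − λ·P(θ)
with P(θ) = θᵀθ (ridge, default, λ = 1) or ‖θ‖₁ (lasso). We use the
squared Euclidean norm for the ridge penalty — the standard form fitted
by every mainstream logistic package — which keeps the objective smooth
and strictly concave. A triple is scored by the mean predicted
probability over its connecting paths, −1 when no path exists. A
candidate drug for a disease — whose true target is unknown, so every
candidate target forms a hypothetical treatment — is scored by pooling
its connecting paths across all candidate targets (each path counted
once) and averaging their probabilities; the arg-max single target is
reported as the putative mechanism. Max-over-targets and
mean-of-per-target-means aggregations are available behind a flag; with
hundreds of candidate targets the max is dominated by single-path
flukes whose probabilities saturate, so pooling is the default.

**Random-walk baseline.** A uniform random walk (transition 1/deg to
each neighbor; M = D·A) on the simple graph induced by the node pairs.
A drug is scored for a disease by the probability of *reaching* the
disease within t steps, computed by making the disease absorbing and
reading the t-step occupancy. The non-absorbing occupancy and a
count-weighted transition variant are available behind flags.

**Evaluation.** Negatives are generated by replacing the drug, target
and disease of gold triples with uniform picks from the role pools,
rejecting corruptions that reproduce a gold triple and (when a graph is
supplied) corruptions with no connecting path, which could contribute no
training row. Ten-fold cross validation partitions the rows at random
into equal folds and reports precision/recall/F over pooled test
predictions (per-fold values are also recorded). The rediscovery test
hides each disease's known drug among 99 random decoys, ranks all 100
candidates, and reports the mean rank and hits@10; ties receive the
worst rank of their tie group, and an unconnected known drug is assigned
rank 101.

## Numerical choices

- The ridge objective is maximized with a trust-region Newton method
  (analytic gradient and Hessian-vector products) from a zero start;
  raw-count features are poorly conditioned and quasi-Newton methods
  converge too slowly here. Internally the fit runs on column-rescaled
  features with the penalty mapped so the optimum is exactly the
  original one (an exact reparametrization, not standardization — the
  reported weights are on the raw-count scale). The trust-region solver
  can report a stall at the optimum, so convergence is additionally
  judged by the gradient norm relative to its starting value
  (tolerance 1e−6).
- The lasso objective is maximized by FISTA (proximal gradient with
  Nesterov momentum); the step size comes from a power-iteration bound
  on ‖X‖₂²/4. Soft-thresholding handles the non-smooth penalty exactly.
- σ(z) is evaluated with `scipy.special.expit` and log-likelihoods via
  `logaddexp`, so logits of magnitude 700+ neither overflow nor lose the
  objective to −∞.
- Path enumeration is a depth-first search over sorted neighbor lists,
  pruned by breadth-first distance to the disease; enumeration order is
  therefore deterministic (lexicographic in the node sequence), and the
  per-triple cap (default 10,000 paths) takes a reproducible prefix.
- Ranking breaks score ties pessimistically (a tied drug receives the
  worst rank in its group) and orders listings by drug identifier.

## The synthetic benchmark

No public corpus at desk scale carries the structure the method needs
(tens of millions of predications, curated therapy triples), so the
package ships a generator that emulates it:

- **Entities.** Role nodes — one drug, one target and one disease per
  planted triple (720 each by default: 700 training + 20 held out for
  rediscovery) — plus a 1,400-node intermediate layer. Each entity
  draws a sparse semantic-type profile from a symmetric Dirichlet
  (α = 0.15) over the K types. No drug, target or disease is reused
  across triples, so the therapy signal lives in the joint combination,
  which a path feature can see and a single node cannot.
- **Background.** Preferential attachment inside the intermediate layer
  (heavy-tailed degrees, emulating hub concepts of the literature), then
  every role node attaches to the same fixed number of intermediates
  (12). The uniform attachment matters: in mined literature graphs every
  curated drug or disease is well covered, and if background degree
  varied across role nodes, the path-connectivity requirement on
  sampled negatives would select well-wired entities and create
  spurious per-entity class priors. Pairs carry 1–3 relations drawn from
  a Zipf-tilted distribution with occurrence counts 2–4, so they survive
  the occurrence filter; a sprinkle of singleton predications is
  injected to give the filter real work.
- **Planted therapies.** Each gold triple is wired with `n_parallel = 2`
  drug–intermediate–target and target–intermediate–disease routes
  (occasionally also the direct edges), the intermediates sampled from
  the existing layer with degree-proportional weights so planted-route
  interiors resemble the hub-biased interiors of background paths. The
  background component of every planted edge is emitted by the same
  routine as the background graph, and is skipped entirely when the
  pair already has an edge.
- **Signal.** At signature strength s > 1, each planted edge receives
  2·(s−1) extra predication batches (three records each) whose relation
  labels and entity types are drawn from a small signature subset of the
  vocabulary with probability 1 − 1/s²; the signature relations come
  from the rare tail of the Zipf ranking, as therapy-specific relations
  are rare in the ambient literature. At s = 1 nothing is added, so
  planted wiring is distributionally exchangeable with background wiring
  and the benchmark is an honest null: positives and corrupted negatives
  differ only in which random entities they connect.
- **Balanced training sets.** `make_training_examples` subsamples
  positive rows and quota-matches the negative rows' drug/target/disease
  marginals and their interior-mass histogram (a 10-bucket quantile
  grid) to the positives'. With a finite entity pool a linear model can
  otherwise exploit per-entity appearance imbalance and the size bias of
  background paths toward hub interiors — rejection-sampling artifacts
  of desk scale, absent at literature scale where essentially every
  corruption is path-connected and no single hub dominates.

What passing tests on this benchmark show: that the pipeline recovers a
semantic-type path signal planted at realistic graph statistics, at
chance level when no signal exists, and that path-feature scoring beats
uniform-walk reachability when the signal lives in type distributions
rather than topology. What they cannot show: performance on real
literature, where extraction noise is correlated with entity frequency,
semantic types are not exchangeable labels, and therapy paths share
mechanism across triples.

## Problem sizes

The shipped defaults (700 planted triples plus 20 held out, ~3,500
entities, ~38,000 node pairs, ~350,000 predications, 4,000 training
rows) were chosen so
that a full generate–train–evaluate cycle, the ten-fold cross
validations at both signature strengths and the 20-disease rediscovery
benchmark run comfortably on a single CPU. Real literature graphs are
three to four orders of magnitude larger; nothing in the implementation
assumes the desk scale, and the path cap plus the distance-pruned
search are the components that keep large graphs tractable.

## Known limitations

- Path enumeration is exhaustive up to ℓ; on hub-dense graphs the cap,
  not the length bound, is the effective limit, and capped triples are
  scored on a deterministic prefix of their paths.
- The logistic model is linear in raw counts; it cannot express "all
  slots must carry signal" exactly, only additively.
- The generator plants signal in type/relation *distributions*. Signals
  in topology alone (e.g. shorter therapy paths) would favor the
  random-walk baseline instead and are deliberately not emulated.
- Negative sampling rejects pathless corruptions with a bounded retry;
  at background densities far below the default, sampling can stall and
  raises rather than silently biasing the training set.
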