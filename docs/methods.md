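# Methods

## Model

`mdsim` treats each knowledge domain as a rooted subsumption DAG of terms
(`is_a` edges, child → parent; `part_of` optionally included) and each
resource as a set of term annotations drawn from several such domains.
Similarity between resources is always a groupwise measure between their
annotation sets; multi-domain comparison is obtained by *lifting* a
single-ontology groupwise measure rather than by defining a new one:

- **baseline(d)**: the measure applied to the two resources' annotations
  in domain d only; 0 when either side has none.
- **aggregative**: the measure applied per domain, averaged over the
  domains where *both* resources are annotated.  Domains missing from
  either resource are excluded from the average rather than scored 0 —
  with sparse coverage an absent domain carries no evidence either way,
  and scoring it 0 would systematically punish sparsely annotated
  resources.  The weighted variant weights each domain by the total number
  of annotations the two resources carry in it.
- **integrative**: all domain ontologies are merged into one DAG and the
  measure applied once to the full annotation sets.  Terms with identical
  ids across sources are unified (their children pool, so subclasses from
  different domains gain a common non-root ancestor); if the sources share
  one common root id it is reused, otherwise a fresh root
  (`MULTI:0000000`) subsumes every former root.  No alignment beyond
  identical-id unification is attempted: two distinct ids that denote the
  same real-world concept remain distinct nodes.

### Information content

The corpus estimator is the classical negative log of propagated relative
annotation frequency: freq(t) counts (resource, annotation) pairs at t or
any descendant, IC(t) = −ln(freq(t)/total pairs), natural log, roots pinned
at 0.  Terms never observed receive the maximum observed IC — this keeps
every value finite while preserving the rarity ordering; any constant above
the observed range would do, and the cap avoids manufacturing similarity
out of unobserved structure.  A structural fallback,
IC(t) = 1 − ln(1+|desc(t)|)/ln(|terms|), covers domains with no corpus.
Resnik scores are divided by the relevant ontology's IC_max before any
cross-domain aggregation (merged-ontology IC_max in the integrative
setting): unnormalized MICA ICs from ontologies of different depth and
annotation density are not commensurable under averaging.  The flag
`normalize_resnik=False` restores raw Resnik for single-domain use.

### ML-KNN evaluation

The evaluation asks how well a similarity matrix supports predicting one
target domain's labels from the remaining domains.  Target-domain
annotations are removed from all similarity inputs first — predicting
labels from a matrix that encodes them would be circular.  Evaluation is
leave-one-out: for each held-out resource, priors
P(H_ℓ) = (s + n_ℓ)/(2s + m_train) and the neighbourhood-count
conditionals P(E_j|H_ℓ) are estimated from the other m−1 resources only
(their k-neighbourhoods are likewise computed within the training set),
and the held-out resource's posterior follows by Bayes' rule.  Smoothing
s = 1 (the estimator's customary Laplace value).  k-neighbourhoods break
similarity ties by ascending resource id; label rankings break posterior
ties by ascending label id — both make the whole pipeline deterministic.
The label space defaults to labels observed in the corpus; a
`full_ontology` mode ranks every non-root term of the target ontology
instead (it inflates the coverage and ranking-loss denominators and is
off by default).

Five metrics summarize a run: Hamming loss (symmetric difference of the
score>0.5 prediction and truth over the label space), one-error (top
label wrong), coverage (how deep the ranking must go to find all true
labels, 0-based), ranking loss (fraction of wrongly ordered (true, false)
pairs), average precision (mean precision at the ranks of true labels).
H_p counts, over all (measure, metric, k) runs, those where at least p
multi-domain settings perform *strictly* better than the best baseline; a
baseline tied into the top p therefore blocks the count, the conservative
reading of multi-domain dominance.

## Synthetic data

The generator emulates the *structure* of a multi-domain annotation corpus,
not any real ontology's content: one random rooted DAG per domain (each
term attaches to a random parent above the depth limit, with a 25% second
parent), per-domain coverage probabilities, annotation volumes of
1 + Poisson(mean−1) distinct terms, optional verbatim id sharing between
two domains to exercise merge unification, and a dependency rule that maps
each informative-domain term to one target-domain label via a fixed
bijective shift — with probability equal to the rule strength the mapped
label is emitted, otherwise a uniformly random one.  All draws come from a
single seeded generator; OBO and TSV serializations are sorted, so equal
seeds give byte-identical files.

Two canned conditions:

- `epidemiology_like_spec`: 7 domains, m = 204, coverages
  (0.01, 0.67, 0.24, 0.01, 0.51, 0.48, 0.23) and volumes
  (1.0, 1.76, 1.0, 1.0, 3.55, 1.0, 1.06) shaped like a published
  epidemiology annotation corpus, a disease-like target (D1) and a strong
  but noisy symptom-like dependency (D4, strength 0.7).  A corpus-shape
  smoke fixture only; it does not reproduce any real dataset's numbers.
- `dependency_recovery_spec`: m = 200, three source domains + one target,
  k-NN recovery conditions.  D0 and D1 determine the target labels
  (strength 1.0 by default), D2 is noise at coverage 0.3, all domains flat
  (depth 1) with 7 usable terms (the noise pool likewise).  Flat domains
  make resource similarity coincide with the term identity the rule
  encodes, so the experiment isolates the lifting machinery.  The planted
  signal is split across *two* domains deliberately: with a single
  informative domain and equal-coverage noise domains, a neighbour
  matching a noise term scores exactly as high as one matching the
  informative term, so ~2/3 of every neighbourhood is noise and no lifting
  — however correct — can recover the labels at k = 3; that failure would
  measure the fixture, not the method.  Sparse noise coverage mirrors the
  real corpora this emulates, where most domains cover well under half the
  resources.

What passing the recovery experiment shows: the liftings propagate exactly
the cross-domain signal planted in the generator.  What it does not show:
performance on real corpora, where annotation noise, correlated domains,
deep term hierarchies and label maps that respect the hierarchy all blur
the planted-signal picture.

## Numerical and degenerate-input choices

- Similarity of an empty annotation set is an "undefined" sentinel
  consumed by the liftings (excluded from aggregative averages; 0 for
  baselines and no-shared-domain pairs).
- Lin similarity is 0 when IC(t₁)+IC(t₂) = 0; simGIC with an all-zero-IC
  union is 1 for identical closures, else 0; normalized Resnik is 0 when
  IC_max = 0.
- MICA ties resolve to the lexicographically smallest term id; terms with
  no common ancestor (disjoint graphs queried without merging) yield the
  sentinel (None, 0.0).
- Obsolete terms stay in the graph as isolated nodes so `alt_id` /
  `replaced_by` resolution works, but are excluded from closures.
- A single-term graph has intrinsic IC 0; a corpus with no resolvable
  annotations for a graph is a configuration error, not an empty table.
- Volume statistics average over covered resources only, the only reading
  under which a domain annotating one resource once has volume 1.0.

## Problem sizes

The shipped experiments use m ≤ 204 resources, ≤ 40 terms per domain and
k ≤ 5; the oracle-equivalence suite uses 200 random instances of ≤ 20
terms and sets of ≤ 8.  These sizes exercise every code path while the
full test suite and the acceptance script each finish in seconds on one
CPU; nothing in the implementation caps larger inputs (the similarity
matrix is O(m²) groupwise calls, ML-KNN leave-one-out O(m²·k·|labels|)).

## Known limitations

- Identical-id unification is the only cross-ontology equivalence the
  merge recognizes; semantically equivalent concepts with different ids
  stay separate (the classical cell-concept collision).
- Cross-reference (xref) semantics, OWL reasoning and logical definitions
  are out of scope; only `is_a` (optionally `part_of`) edges are read.
- The evaluation protocol is leave-one-out label prediction; no
  train/test split or significance testing is provided.
- The "Max_in" ranking statistic sometimes reported alongside the five
  canonical multi-label metrics has no standard definition and is not
  implemented.
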