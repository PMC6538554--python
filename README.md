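# mdsim — multi-domain semantic similarity for annotated biomedical resources

Biomedical resources are increasingly annotated with concepts from *several*
ontologies at once: an epidemiology dataset may carry disease, symptom,
transmission-mode, environment and vaccine terms side by side.  Classical
ontology-based semantic similarity compares two resources within a single
ontology, so it either discards most of that metadata or cannot compare
resources annotated in different domains at all.  `mdsim` is for anyone who
needs resource-by-resource similarity over such multi-domain annotation
corpora — e.g. to back "related resources" retrieval or to recommend new
annotations — and for evaluating whether using all domains actually helps.

## What it computes

Single-ontology *groupwise* measures between two annotation sets A and B:

- **Resnik + BMA** — best-match average of pairwise Resnik similarity,
  sim(t₁,t₂) = IC(MICA(t₁,t₂)), with IC(t) = −ln p̂(t) the information
  content from propagated annotation frequencies (optionally rescaled by
  IC_max so scores live in [0,1]);
- **Lin + BMA** — pairwise 2·IC(MICA)/(IC(t₁)+IC(t₂)) under the same BMA;
- **simUI** — Jaccard overlap |Anc(A) ∩ Anc(B)| / |Anc(A) ∪ Anc(B)| of the
  ancestor closures;
- **simGIC** — the IC-weighted version, Σ_{Anc∩} IC / Σ_{Anc∪} IC.

Two liftings turn any of these into a multi-domain measure:

- **aggregative** — score each shared domain with the single-ontology
  measure and average, either uniformly (*raw*) or weighted by the number
  of annotations the pair carries in each domain (*weighted*);
- **integrative** — merge all domain ontologies under a common root
  (identical term ids are unified; otherwise a fresh root subsumes every
  domain root) and apply the measure once to the full annotation sets.

Single-domain *baseline* settings restrict the comparison to one domain.

To judge the settings, `mdsim` predicts one target domain's annotations
from the others: a leave-one-out **ML-KNN** classifier scores every
candidate label from its frequency among each resource's k most similar
neighbours, and five multi-label metrics (Hamming loss, one-error,
coverage, ranking loss, average precision) summarize each (setting,
measure, k) run.  The **H_p** statistic counts the runs in which the p
best-performing settings are all multi-domain ones.

Because real multi-domain corpora of this kind are not freely
redistributable, the package ships a seeded synthetic generator that
emulates their structure — several orthogonal ontologies, sparse and
uneven per-domain coverage, and a target domain whose labels depend on the
other domains' annotations.

## Worked example

```python
from mdsim import (MeasureSpec, SettingSpec, compute_hp,
                   dependency_recovery_spec, generate, run_experiment)

ontologies, corpus = generate(dependency_recovery_spec(seed=1))
settings = [
    SettingSpec(mode="integrative"),
    SettingSpec(mode="aggregative_raw"),
    SettingSpec(mode="aggregative_weighted"),
    SettingSpec(mode="baseline", baseline_domain="D2"),   # noise domain
]
report = run_experiment(corpus, ontologies, settings,
                        [MeasureSpec(groupwise="resnik_bma")],
                        [1, 3, 5], target_domain="D3")
print(report.frame.round(3).to_string(index=False))
print(compute_hp(report).to_frame().to_string(index=False))
```

The fixture plants a deterministic dependency: the target domain D3's
labels are a function of the D0/D1 annotations, while D2 is uninformative
noise.  Output:

```
             setting    measure  k  hamming_loss  one_error  coverage  ranking_loss  average_precision
         integrative resnik_bma  1         0.032      0.070     1.330         0.049              0.946
         integrative resnik_bma  3         0.026      0.015     1.060         0.017              0.975
         integrative resnik_bma  5         0.029      0.010     0.985         0.009              0.986
     aggregative_raw resnik_bma  1         0.004      0.005     0.950         0.005              0.995
     aggregative_raw resnik_bma  3         0.010      0.000     0.955         0.005              0.993
     aggregative_raw resnik_bma  5         0.014      0.000     0.975         0.007              0.991
aggregative_weighted resnik_bma  1         0.004      0.005     0.950         0.005              0.995
aggregative_weighted resnik_bma  3         0.010      0.000     0.955         0.005              0.993
aggregative_weighted resnik_bma  5         0.014      0.000     0.975         0.007              0.991
         baseline:D2 resnik_bma  1         0.272      0.685     4.260         0.510              0.474
         baseline:D2 resnik_bma  3         0.276      0.640     3.935         0.450              0.512
         baseline:D2 resnik_bma  5         0.286      0.665     4.250         0.506              0.474
 H_1  H_2  H_3  runs
  15   15   15    15
```

Reading it: the multi-domain settings recover the planted dependency almost
perfectly (average precision ≈ 0.95–0.99 — the true labels sit at the top
of the predicted ranking), while the baseline restricted to the noise
domain stays near chance (≈ 0.47–0.51).  H_1 = H_2 = H_3 = 15 means that in
every one of the 15 runs (5 metrics × 3 values of k) the three best
settings were all multi-domain.

The same pipeline runs from the shell on OBO + TSV inputs or a synthetic
config; see `mdsim --help` (subcommands `generate`, `stats`, `similarity`,
`evaluate`, `hp`).

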