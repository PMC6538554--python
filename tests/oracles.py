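"""Independent brute-force reference implementations used only in tests.

Everything here deliberately avoids the package's own graph/closure code:
reachability is done by boolean matrix powers, groupwise measures by naive
double loops over explicitly enumerated closures, ML-KNN by plain-dict
counting, and the ranking metrics by direct definition over score lists.
"""

from __future__ import annotations

import numpy as np


def bf_ancestors(graph, term):
    """Reflexive transitive closure via boolean matrix powers."""
    ids = sorted(graph.terms)
    idx = {t: i for i, t in enumerate(ids)}
    n = len(ids)
    adj = np.zeros((n, n), dtype=bool)
    for child, parent in graph.graph.edges():
        adj[idx[child], idx[parent]] = True
    reach = np.eye(n, dtype=bool)
    for _ in range(n):
        new = reach | (reach @ adj)
        if (new == reach).all():
            break
        reach = new
    return {ids[j] for j in np.nonzero(reach[idx[term]])[0]}


def bf_mica(graph, ic, t1, t2):
    common = bf_ancestors(graph, t1) & bf_ancestors(graph, t2)
    if not common:
        return None, 0.0
    best_ic = max(ic.get(t, 0.0) for t in common)
    best = min(t for t in common if ic.get(t, 0.0) == best_ic)
    return best, best_ic


def bf_bma(pairsim, a_set, b_set):
    a_set, b_set = list(set(a_set)), list(set(b_set))
    fwd = sum(max(pairsim(a, b) for b in b_set) for a in a_set) / len(a_set)
    bwd = sum(max(pairsim(a, b) for a in a_set) for b in b_set) / len(b_set)
    return (fwd + bwd) / 2.0


def bf_closure(graph, terms):
    out = set()
    for t in terms:
        out |= bf_ancestors(graph, t)
    return out


def bf_simui(graph, a_set, b_set):
    ca, cb = bf_closure(graph, a_set), bf_closure(graph, b_set)
    return len(ca & cb) / len(ca | cb)


def bf_simgic(graph, ic, a_set, b_set):
    ca, cb = bf_closure(graph, a_set), bf_closure(graph, b_set)
    num = sum(ic.get(t, 0.0) for t in ca & cb)
    den = sum(ic.get(t, 0.0) for t in ca | cb)
    if den == 0.0:
        return 1.0 if ca == cb else 0.0
    return num / den


def bf_neighborhoods(resource_ids, scores, k):
    out = {}
    for i, r in enumerate(resource_ids):
        others = [
            (-(scores[i][j]), other, j)
            for j, other in enumerate(resource_ids)
            if j != i
        ]
        others.sort()
        out[r] = [other for _, other, _ in others[:k]]
    return out


def bf_metrics(rankings, truths, label_space):
    """Direct-definition multi-label metrics from explicit rankings.

    rankings: resource -> list of labels best-first; truths: resource ->
    set of true labels; predictions for hamming are supplied separately.
    """
    n = len(rankings)
    one_error = sum(1 for r in rankings if rankings[r][0] not in truths[r]) / n
    coverage = (
        sum(max(rankings[r].index(l) for l in truths[r]) for r in rankings) / n
    )
    rloss = 0.0
    avgprec = 0.0
    for r, ranking in rankings.items():
        pos = {l: i + 1 for i, l in enumerate(ranking)}
        true = truths[r]
        false = set(label_space) - true
        if false:
            wrong = sum(1 for t in true for f in false if pos[f] < pos[t])
            rloss += wrong / (len(true) * len(false))
        avgprec += (
            sum(
                len([o for o in true if pos[o] <= pos[l]]) / pos[l] for l in true
            )
            / len(true)
        )
    return {
        "one_error": one_error,
        "coverage": coverage,
        "ranking_loss": rloss / n,
        "average_precision": avgprec / n,
    }


def bf_mlknn_posterior(train_labels, train_neighbor_counts, test_count, k, s):
    """Closed-form ML-KNN posterior for one label from explicit counts.

    train_labels: list of 0/1 for each training resource; counts: the
    number of that resource's k neighbours carrying the label; test_count:
    the held-out resource's neighbourhood count.
    """
    m = len(train_labels)
    n_pos = sum(train_labels)
    prior = (s + n_pos) / (2 * s + m)
    c_pos = [0] * (k + 1)
    c_neg = [0] * (k + 1)
    for y, c in zip(train_labels, train_neighbor_counts):
        (c_pos if y else c_neg)[c] += 1
    p_e_h = (s + c_pos[test_count]) / (s * (k + 1) + sum(c_pos))
    p_e_nh = (s + c_neg[test_count]) / (s * (k + 1) + sum(c_neg))
    num = prior * p_e_h
    return num / (num + (1 - prior) * p_e_nh)
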