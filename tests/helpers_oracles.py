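"""Independent brute-force reference implementations for oracle tests.

These deliberately share no code with the package: scores are computed by
enumerating every tagged drug, sorting a plain Python list, and summing a
slice; rankings by evaluating all tags and sorting with an explicit tie
key; the leave-one-out harness by rebuilding the training list per query.
"""

from __future__ import annotations


def brute_score(query, tag, training, weight, k):
    weights = [weight(query, d.drug_id) for d in training.drugs if tag in d.indications]
    weights.sort(reverse=True)
    total = 0.0
    for w in weights[:k]:
        total += w
    return total


def brute_rank(query, training, weight, k, catalog):
    scored = []
    for idx, tag in enumerate(catalog.tags):
        s = brute_score(query, tag, training, weight, k)
        if s > 0:
            scored.append((tag, s, idx))
    scored.sort(key=lambda x: (-x[1], x[2]))
    return [(tag, s) for tag, s, _ in scored]


def brute_sequential(query, training, interactions, similarity, k_int, k_sim):
    by_int = brute_rank(query, training, interactions.get, k_int, training.catalog)
    if by_int:
        return by_int
    return brute_rank(query, training, similarity.get, k_sim, training.catalog)


def brute_jackknife_acc1(dataset, interactions, similarity, k_int, k_sim):
    hits = 0
    for d in dataset.drugs:
        training = dataset.without(d.drug_id)
        ranking = brute_sequential(d.drug_id, training, interactions, similarity,
                                   k_int, k_sim)
        if ranking and ranking[0][0] in d.indications:
            hits += 1
    return hits / len(dataset.drugs)


def brute_independent_sets(ids, sim, threshold):
    """All maximal independent sets of the thresholded similarity graph,
    by exhaustive subset enumeration (fixtures of ~15 drugs at most)."""
    n = len(ids)
    edges = {
        (i, j)
        for i in range(n)
        for j in range(i + 1, n)
        if sim(ids[i], ids[j]) >= threshold
    }

    def independent(subset):
        return not any((i, j) in edges for i in subset for j in subset if i < j)

    sets = []
    for mask in range(1 << n):
        subset = [i for i in range(n) if mask >> i & 1]
        if independent(subset):
            sets.append(frozenset(ids[i] for i in subset))
    maximal = [s for s in sets if not any(s < t for t in sets)]
    return maximal
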