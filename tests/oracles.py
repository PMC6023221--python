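"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's array core: plain Python loops
evaluating the linking predicate pairwise, exhaustive enumeration of
resampling nulls, and direct arithmetic.
"""

from itertools import combinations, permutations


def brute_force_clusters(features, max_gap_bp=200_000, max_intervening=8, min_size=2):
    """Maximal chains of linked consecutive family features.

    ``features``: iterable of (id, scaffold, start, end, is_family).
    Returns (clusters, isolated) with clusters as lists of ids in
    positional order.
    """
    feats = sorted(features, key=lambda f: (f[1], f[2], f[3], f[0]))
    by_scaffold = {}
    for f in feats:
        by_scaffold.setdefault(f[1], []).append(f)
    clusters, isolated = [], set()
    for scaffold_feats in by_scaffold.values():
        fam = [f for f in scaffold_feats if f[4]]
        bg = [f for f in scaffold_feats if not f[4]]
        links = []
        for a, b in zip(fam, fam[1:]):
            gap = b[2] - a[3]
            intervening = sum(1 for g in bg if a[3] < g[2] < b[2])
            links.append(gap <= max_gap_bp and intervening <= max_intervening)
        i = 0
        while i < len(fam):
            j = i
            while j < len(fam) - 1 and links[j]:
                j += 1
            chain = [f[0] for f in fam[i : j + 1]]
            if len(chain) >= min_size:
                clusters.append(chain)
            else:
                isolated.update(chain)
            i = j + 1
    return clusters, isolated


def clustered_fraction(features, family_ids, **kw):
    """Fraction of ``family_ids`` in a brute-force cluster when exactly that
    set plays the family role."""
    family_ids = set(family_ids)
    relabeled = [(f[0], f[1], f[2], f[3], f[0] in family_ids) for f in features]
    clusters, _ = brute_force_clusters(relabeled, **kw)
    n_clustered = sum(len(c) for c in clusters)
    return n_clustered / len(family_ids)


def exact_clustering_p(features, all_ids, n_sample, observed, **kw):
    """Exact resampling p-value by enumerating every subset of size
    ``n_sample``: P(clustered fraction >= observed)."""
    subsets = list(combinations(sorted(all_ids), n_sample))
    hits = sum(
        1 for s in subsets if clustered_fraction(features, s, **kw) >= observed - 1e-12
    )
    return hits / len(subsets)


def shared_fraction(cluster_of, labels):
    """Observed co-expression statistic by direct counting: over labelled
    items inside a physical cluster, the fraction sharing their label with
    another item of the same cluster."""
    in_cluster = [i for i in labels if cluster_of.get(i) is not None]
    n_share = 0
    for i in in_cluster:
        if any(
            j != i and cluster_of.get(j) == cluster_of[i] and labels[j] == labels[i]
            for j in labels
        ):
            n_share += 1
    return n_share / len(in_cluster)


def exact_coexpression_p(cluster_of, labels, observed):
    """Exact permutation p-value over all distinct orderings of the label
    multiset."""
    ids = sorted(labels)
    values = [labels[i] for i in ids]
    perms = set(permutations(values))
    hits = 0
    for perm in perms:
        stat = shared_fraction(cluster_of, dict(zip(ids, perm)))
        if stat >= observed - 1e-12:
            hits += 1
    return hits / len(perms)
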