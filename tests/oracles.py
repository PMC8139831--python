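"""Independent brute-force oracles used to validate the fast implementations.

Deliberately written without spatial indexing or vectorized shortcuts so
they share no code path with the library.
"""

from math import comb, exp

import numpy as np


def brute_synapse_similarity(a, b, sigma=2000.0, omega=2000.0):
    """Directed kernel score by explicit nested loops over synapse pairs."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    total = 0.0
    for s in a:
        dists = [float(np.sqrt(((s - k) ** 2).sum())) for k in b]
        j = int(np.argmin(dists))  # ties -> lowest index
        d_sk = dists[j]
        n_is = sum(
            1 for t in a if float(np.sqrt(((s - t) ** 2).sum())) <= omega
        ) / len(a)
        n_jk = sum(
            1 for t in b if float(np.sqrt(((b[j] - t) ** 2).sum())) <= omega
        ) / len(b)
        total += exp(-(d_sk**2) / (2 * sigma**2)) * exp(
            -abs(n_is - n_jk) / (n_is + n_jk)
        )
    return total / len(a)


def brute_connectivity(connectors, neuron_ids):
    """Per-row contact tally by explicit iteration."""
    index = {nid: k for k, nid in enumerate(neuron_ids)}
    counts = np.zeros((len(neuron_ids), len(neuron_ids)), dtype=int)
    for c in connectors:
        for nid, _ in c.post_partners:
            if c.pre_neuron in index and nid in index:
                counts[index[c.pre_neuron], index[nid]] += 1
    return counts


def bfs_distances(binary):
    """All-pairs undirected shortest paths via networkx BFS."""
    import networkx as nx

    n = binary.shape[0]
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(n):
            if binary[i, j]:
                g.add_edge(i, j)
    out = np.full((n, n), np.inf)
    for i, lengths in nx.all_pairs_shortest_path_length(g):
        for j, d in lengths.items():
            out[i, j] = d
    return out


def brute_cohort_frequency(binary, cohorts):
    """pair_both cohort connection frequency by triple loop."""
    labels = list(cohorts)
    successes = 0
    total = 0
    for a in labels:
        members = cohorts[a]
        if len(members) < 2:
            continue
        for c in labels:
            if c == a:
                continue
            for x in range(len(members)):
                for y in range(x + 1, len(members)):
                    total += 1
                    mx, my = members[x], members[y]
                    hit_x = any(binary[mx, t] for t in cohorts[c])
                    hit_y = any(binary[my, t] for t in cohorts[c])
                    if hit_x and hit_y:
                        successes += 1
    return successes / total


def exact_ranksum_p(x, y):
    """Exact two-sided rank-sum p by enumeration of all group assignments."""
    from itertools import combinations

    pooled = sorted(x + y)
    ranks = {v: r + 1 for r, v in enumerate(pooled)}
    obs = sum(ranks[v] for v in x)
    n = len(pooled)
    stats = [
        sum(pooled.index(v) + 1 for v in combo)
        for combo in combinations(pooled, len(x))
    ]
    mean = np.mean(stats)
    extreme = sum(1 for s in stats if abs(s - mean) >= abs(obs - mean))
    return extreme / comb(n, len(x))
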