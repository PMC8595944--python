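"""Independent test oracles shared across test modules.

These deliberately avoid the code paths they check: the Mann-Whitney p-value
is obtained by enumerating all group assignments, and the best modularity by
scoring every partition of the node set.
"""

import itertools

import networkx as nx
import numpy as np

from somnospec.network import BootstrapCorrelationMatrix


def make_matrix(nodes, entries, default=0.0):
    """Build a BootstrapCorrelationMatrix from sparse median entries."""
    n = len(nodes)
    med = np.full((n, n), default)
    np.fill_diagonal(med, 1.0)
    for (a, b), v in entries.items():
        i, j = nodes.index(a), nodes.index(b)
        med[i, j] = med[j, i] = v
    return BootstrapCorrelationMatrix(
        nodes=tuple(nodes),
        median=med,
        p2_5=med - 0.05,
        p97_5=med + 0.05,
        n_valid=np.full((n, n), 100),
        n_boot=100,
        n_subsample=20,
        seed=0,
    )


def enumerated_mwu_p(x, y):
    """Exact two-sided Mann-Whitney p by enumerating all group assignments
    (tie-free inputs only)."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    observed = sum((a > b) for a in x for b in y)
    n = len(pooled)
    mean_u = n1 * (n - n1) / 2
    stats = []
    for combo in itertools.combinations(range(n), n1):
        first = pooled[list(combo)]
        rest = np.delete(pooled, list(combo))
        stats.append(sum((a > b) for a in first for b in rest))
    stats = np.asarray(stats)
    extreme = np.abs(stats - mean_u) >= abs(observed - mean_u) - 1e-9
    return extreme.mean()


def set_partitions(seq):
    if not seq:
        yield []
        return
    head, *rest = seq
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [part[i] | {head}] + part[i + 1 :]
        yield part + [{head}]


def exhaustive_modularity(g):
    """Best weighted modularity over all partitions (<= 8 nodes)."""
    best = -np.inf
    for part in set_partitions(list(g.nodes)):
        q = nx.algorithms.community.modularity(g, part, weight="abs_weight")
        best = max(best, q)
    return best
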