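"""Independent oracles shared by the test modules."""

import numpy as np

from dacuity._utils import edge_index, unvectorize_edges
from dacuity.network import modularity
from dacuity.synthetic import _block_partition


def block_graph(n_nodes, n_modules, within=0.25, between=0.02):
    part = _block_partition(n_nodes, n_modules)
    i, j = edge_index(n_nodes)
    return unvectorize_edges(np.where(part[i] == part[j], within, between), n_nodes), part


def brute_force_best_modularity(W, gamma=1.0):
    """Exhaustive search over all set partitions of the nodes."""
    n = W.shape[0]

    def partitions(nodes):
        if not nodes:
            yield []
            return
        first, rest = nodes[0], nodes[1:]
        for part in partitions(rest):
            for k in range(len(part)):
                yield part[:k] + [[first] + part[k]] + part[k + 1:]
            yield [[first]] + part

    best = -np.inf
    for part in partitions(list(range(n))):
        labels = np.empty(n, int)
        for c, block in enumerate(part):
            labels[block] = c
        best = max(best, modularity(W, labels, gamma))
    return best
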