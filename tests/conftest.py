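import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from segcoex import ExpressionMatrix, GenomeLayout, LayoutElement, SampleDesign


@pytest.fixture
def rng():
    return np.random.default_rng(20170921)


def make_matrix(values, element_ids=None, sample_ids=None, scale="linear",
                background_ids=()):
    values = np.asarray(values, dtype=float)
    element_ids = element_ids or [f"g{i+1}" for i in range(values.shape[0])]
    sample_ids = sample_ids or [f"s{j+1}" for j in range(values.shape[1])]
    df = pd.DataFrame(values, index=element_ids, columns=sample_ids)
    return ExpressionMatrix(df, scale=scale, background_ids=frozenset(background_ids))


def make_layout(n, circular=True, strands=None, prefix="g"):
    """n equally spaced genes g1..gn on a toy chromosome."""
    strands = strands or ["+"] * n
    elements = [
        LayoutElement(f"{prefix}{i+1}", 1000 * i + 1, 1000 * i + 900, strands[i])
        for i in range(n)
    ]
    return GenomeLayout(elements, circular=circular, genome_length=1000 * n)


def make_network(nodes, edges):
    g = nx.Graph()
    g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    return g


def make_design(conditions, n_reps=3, reference=None):
    mapping = {
        f"{c}_r{r+1}": c for c in conditions for r in range(n_reps)
    }
    return SampleDesign(mapping, reference or conditions[0])


# ----------------------------------------------------------------- oracles
# Independent brute-force reference implementations, deliberately built on
# networkx primitives rather than the package's own traversal code.

def brute_force_segments(layout, network, min_len=2, max_len=50, genes_only=True):
    """Test every arc with an independent connectivity check."""
    order = layout.ordered_ids(genes_only=genes_only)
    n = len(order)
    hi = min(max_len, n - 1 if layout.circular else n)
    found = []
    for start in range(n):
        for k in range(max(2, min_len), hi + 1):
            if not layout.circular and start + k > n:
                continue
            members = [order[(start + i) % n] for i in range(k)]
            sub = network.subgraph(members)
            first, last = members[0], members[-1]
            if first in sub and last in sub and nx.has_path(sub, first, last):
                comp = nx.node_connected_component(sub, first)
                found.append((start, tuple(members), frozenset(comp),
                              len(comp) / k))
    return found


def brute_force_dominant(segments, density_min=0.6, apply_density_filter=True):
    """All-pairs dominance over (members, reachable, density) tuples."""
    if apply_density_filter:
        cands = [s for s in segments if s[3] >= density_min]
    else:
        cands = list(segments)
    out = []
    for a in cands:
        dominated = any(
            b is not a and a[2] <= b[2] and a[3] < b[3] for b in cands
        )
        if not dominated:
            out.append(a)
    return out


def random_instance(rng, n=None, edge_prob=None, circular=True):
    """A random layout + Erdos-Renyi network over its genes."""
    n = n if n is not None else int(rng.integers(4, 31))
    edge_prob = edge_prob if edge_prob is not None else float(rng.uniform(0.05, 0.5))
    strands = ["+" if rng.random() < 0.5 else "-" for _ in range(n)]
    layout = make_layout(n, circular=circular, strands=strands)
    nodes = layout.ordered_ids()
    edges = [
        (a, b) for a, b in itertools.combinations(nodes, 2)
        if rng.random() < edge_prob
    ]
    return layout, make_network(nodes, edges)
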