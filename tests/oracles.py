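"""Independent oracles used by the test suite.

Deliberately written with different algorithms/data structures than the
package code paths they check: the flow oracle enumerates simple paths and
optimizes over path variables (vs the package's arc-flow LP), and the TMM
oracle is a plain-Python re-derivation (vs the package's vectorized numpy).
"""

from __future__ import annotations

import math

import networkx as nx
import numpy as np
from scipy.optimize import linprog

from respnet.flowcore import S_KEY, T_KEY, FlowProblem


# ---------------------------------------------------------------------------
# flow: path-decomposition optimum by exhaustive simple-path enumeration
# ---------------------------------------------------------------------------

def path_decomposition_optimum(p: FlowProblem) -> float:
    """Optimal objective via an LP over exhaustively enumerated S->T paths.

    Valid whenever every directed cycle has non-negative cost (true here:
    arc costs are -ln(w) >= 0), so some optimal flow is cycle-free and
    decomposes into simple S->T paths.  Requires at most one arc per ordered
    node pair (the generators used in tests guarantee this).
    """
    G = nx.DiGraph()
    arc_idx: dict[tuple, int] = {}
    for j, a in enumerate(p.arcs):
        assert (a.tail, a.head) not in arc_idx, "oracle requires simple digraph"
        arc_idx[(a.tail, a.head)] = j
        G.add_edge(a.tail, a.head)
    if S_KEY not in G or T_KEY not in G:
        return 0.0
    paths = list(nx.all_simple_paths(G, S_KEY, T_KEY))
    if not paths:
        return 0.0
    n_paths = len(paths)
    c = np.zeros(n_paths)
    A_rows = []
    b_ub = []
    use = {j: [] for j in range(len(p.arcs))}
    for i, path in enumerate(paths):
        cost = 0.0
        for u, v in zip(path[:-1], path[1:]):
            j = arc_idx[(u, v)]
            cost += p.arcs[j].cost
            use[j].append(i)
        c[i] = cost - p.gamma
    for j, users in use.items():
        if not users:
            continue
        row = np.zeros(n_paths)
        row[users] = 1.0
        A_rows.append(row)
        b_ub.append(p.arcs[j].capacity)
    res = linprog(c, A_ub=np.array(A_rows), b_ub=np.array(b_ub),
                  bounds=[(0, None)] * n_paths, method="highs")
    assert res.status == 0, res.message
    return float(res.fun)


def all_path_costs(p: FlowProblem) -> list[float]:
    """Costs (sum of -ln w) of every simple S->T path."""
    G = nx.DiGraph()
    for a in p.arcs:
        G.add_edge(a.tail, a.head, cost=a.cost)
    if S_KEY not in G or T_KEY not in G:
        return []
    out = []
    for path in nx.all_simple_paths(G, S_KEY, T_KEY):
        out.append(sum(G[u][v]["cost"] for u, v in zip(path[:-1], path[1:])))
    return out


def shortest_path_edges(net, source_id: str, target) -> set:
    """Edge keys of the minimum total -ln(weight) path from a source protein
    to a target node, via Dijkstra on an independently built graph."""
    from respnet.interactome import EdgeType, Kind
    G = nx.DiGraph()
    for e in net.edges:
        w = -math.log(e.weight)
        G.add_edge(e.a.key, e.b.key, cost=w, ekey=e.key)
        if e.etype is EdgeType.PPI:
            G.add_edge(e.b.key, e.a.key, cost=w, ekey=e.key)
    src = (source_id, Kind.PROTEIN.value)
    for kind in (Kind.GENE, Kind.PROTEIN, Kind.MIRNA):
        tgt = (target, kind.value)
        if tgt in G:
            break
    path = nx.shortest_path(G, src, tgt, weight="cost")
    return {G[u][v]["ekey"] for u, v in zip(path[:-1], path[1:])}


# ---------------------------------------------------------------------------
# TMM: plain-Python re-derivation
# ---------------------------------------------------------------------------

def _avg_ranks(values: list[float]) -> list[float]:
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def tmm_factors_oracle(X: np.ndarray, trim_M: float = 0.30,
                       trim_A: float = 0.05) -> list[float]:
    """Per-sample TMM factors (geometric mean 1), recomputed from first
    principles with Python loops."""
    n_genes, n_samples = X.shape
    lib = [float(sum(X[:, j])) for j in range(n_samples)]
    uq = [float(np.quantile([X[g, j] / lib[j] for g in range(n_genes)], 0.75))
          for j in range(n_samples)]
    mean_uq = sum(uq) / n_samples
    ref = min(range(n_samples), key=lambda j: abs(uq[j] - mean_uq))

    factors = []
    for j in range(n_samples):
        M, A, V = [], [], []
        for g in range(n_genes):
            o, r = X[g, j], X[g, ref]
            if o <= 0 or r <= 0:
                continue
            po, pr = o / lib[j], r / lib[ref]
            M.append(math.log2(po / pr))
            A.append(0.5 * (math.log2(po) + math.log2(pr)))
            V.append((lib[j] - o) / (lib[j] * o) + (lib[ref] - r) / (lib[ref] * r))
        if not M or max(abs(m) for m in M) < 1e-6:
            factors.append(1.0)
            continue
        n = len(M)
        lo_m, hi_m = math.floor(n * trim_M) + 1, n - math.floor(n * trim_M)
        lo_a, hi_a = math.floor(n * trim_A) + 1, n - math.floor(n * trim_A)
        rm, ra = _avg_ranks(M), _avg_ranks(A)
        num = den = 0.0
        for i in range(n):
            if lo_m <= rm[i] <= hi_m and lo_a <= ra[i] <= hi_a:
                num += M[i] / V[i]
                den += 1.0 / V[i]
        factors.append(2.0 ** (num / den) if den > 0 else 1.0)
    log_gm = sum(math.log(f) for f in factors) / n_samples
    return [f / math.exp(log_gm) for f in factors]
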