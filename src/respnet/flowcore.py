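"""Minimum-cost-flow linear program connecting sources to targets.

A super-source S feeds every usable source protein and a super-sink T drains
every usable target; each interactome edge of weight w becomes an arc of unit
cost -ln(w) (undirected PPIs become two antiparallel arcs).  The LP

    minimize   sum_arcs cost * flow  -  gamma * (total flow out of S)
    subject to flow conservation at every interior node, 0 <= flow <= capacity

rewards routed flow at rate gamma, so the optimum routes flow along
high-probability (low negative-log-weight) paths as long as the marginal path
cost stays below gamma.  Sparsity of the positive-flow subnetwork is a
property of LP vertex optima.  Solved with scipy's HiGHS backend.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy.optimize import linprog
from scipy.sparse import coo_matrix

from .errors import SolverError, ValidationError
from .interactome import (EdgeType, Interaction, Interactome, Kind, Molecule,
                          NodeKey, REGULATORY_ETYPES)

logger = logging.getLogger(__name__)

__all__ = [
    "Arc",
    "FlowProblem",
    "FlowSolution",
    "Subnetwork",
    "build_flow_problem",
    "solve_flow",
    "extract_subnetwork",
    "run_responsenet",
    "node_significance",
]

S_KEY: tuple = ("__S__", "__AUX__")
T_KEY: tuple = ("__T__", "__AUX__")


@dataclass(frozen=True)
class Arc:
    tail: tuple
    head: tuple
    capacity: float
    cost: float
    interaction: Optional[Interaction] = None  # None for auxiliary S/T arcs


@dataclass
class FlowProblem:
    arcs: list[Arc]
    gamma: float
    source_weights: dict[NodeKey, float]
    target_weights: dict[NodeKey, float]
    not_connectable: dict[str, list[str]]
    #: target-copy key -> original node key (duplicated source-and-target nodes)
    copy_of: dict[tuple, NodeKey] = field(default_factory=dict)
    net: Optional[Interactome] = None

    @property
    def nodes(self) -> list[tuple]:
        seen: dict[tuple, None] = {}
        for a in self.arcs:
            seen.setdefault(a.tail)
            seen.setdefault(a.head)
        return list(seen)


@dataclass
class FlowSolution:
    flows: np.ndarray            # aligned with FlowProblem.arcs
    objective: float
    status: str
    solver: str = "scipy-highs"

    def total_source_outflow(self, p: FlowProblem) -> float:
        return float(sum(f for a, f in zip(p.arcs, self.flows) if a.tail == S_KEY))


@dataclass
class Subnetwork:
    """Positive-flow edges mapped back to interactions, with node roles."""

    name: str
    edges: list[tuple[Interaction, float]]
    node_roles: dict[NodeKey, str]          # source | target | connecting
    node_throughput: dict[NodeKey, float]
    connected_sources: list[str]
    connected_targets: list[str]
    config: dict = field(default_factory=dict)
    annotations: dict = field(default_factory=dict)

    @property
    def nodes(self) -> list[Molecule]:
        seen: dict[NodeKey, Molecule] = {}
        for e, _f in self.edges:
            seen.setdefault(e.a.key, e.a)
            seen.setdefault(e.b.key, e.b)
        return list(seen.values())

    @property
    def node_keys(self) -> set[NodeKey]:
        return {m.key for m in self.nodes}

    @property
    def n_connecting(self) -> int:
        """Count of connecting (neither source nor target) nodes — the
        method's novel predictions."""
        return sum(1 for k in self.node_keys
                   if self.node_roles.get(k, "connecting") == "connecting")

    def edge_keys(self) -> set:
        return {e.key for e, _f in self.edges}


# ---------------------------------------------------------------------------
# problem construction
# ---------------------------------------------------------------------------

def _normalize_weights(ids: Sequence[str], weights: Optional[Mapping[str, float]],
                       label: str) -> dict[str, float]:
    if weights:
        w = {i: float(weights.get(i, 1.0)) for i in ids}
        if any(v <= 0 for v in w.values()):
            raise ValidationError(f"{label} weights must be positive")
    else:
        w = {i: 1.0 for i in ids}
    total = sum(w.values())
    return {i: v / total for i, v in w.items()}


def build_flow_problem(
    net: Interactome,
    sources: Sequence[str],
    targets: Sequence[str],
    gamma: float = 10.0,
    edge_capacity: float = 1.0,
    source_weights: Optional[Mapping[str, float]] = None,
    target_weights: Optional[Mapping[str, float]] = None,
) -> FlowProblem:
    """Encode the LP.

    Sources must be PROTEIN nodes of ``net``; targets may be GENE, PROTEIN or
    MIRNA nodes.  Ids absent from the net are listed under
    ``not_connectable`` rather than failing; an empty usable set is fatal.
    S->source and target->T arc capacities carry the (normalized) per-node
    weights.  A node acting as both source and target is duplicated: the
    target copy receives clones of all incoming arcs, so source flow cannot
    shortcut directly into the sink.
    """
    if gamma < 0:
        raise ValidationError("gamma must be non-negative")
    not_conn: dict[str, list[str]] = {"sources": [], "targets": []}

    def resolve(ident: str, kinds: tuple[Kind, ...]) -> Optional[NodeKey]:
        for k in kinds:
            if net.has_node((ident, k.value)):
                return (ident, k.value)
        return None

    src_keys: dict[str, NodeKey] = {}
    for s in dict.fromkeys(sources):
        key = resolve(s, (Kind.PROTEIN,))
        if key is None:
            not_conn["sources"].append(s)
        else:
            src_keys[s] = key
    tgt_keys: dict[str, NodeKey] = {}
    for t in dict.fromkeys(targets):
        key = resolve(t, (Kind.GENE, Kind.PROTEIN, Kind.MIRNA))
        if key is None:
            not_conn["targets"].append(t)
        else:
            tgt_keys[t] = key
    if not src_keys:
        raise ValidationError("no usable source nodes in interactome")
    if not tgt_keys:
        raise ValidationError("no usable target nodes in interactome")
    if not_conn["sources"] or not_conn["targets"]:
        logger.info("not connectable: %d sources, %d targets",
                    len(not_conn["sources"]), len(not_conn["targets"]))

    sw = _normalize_weights(list(src_keys), source_weights, "source")
    tw = _normalize_weights(list(tgt_keys), target_weights, "target")

    overlap = set(src_keys.values()) & set(tgt_keys.values())
    copy_of: dict[tuple, NodeKey] = {}

    def head_key(k: NodeKey) -> tuple:
        # arcs into an overlap node are cloned onto its target copy as well
        return k

    arcs: list[Arc] = []
    for e in net.edges:
        cost = -math.log(e.weight)
        heads: list[tuple[tuple, tuple]] = []  # (tail, head) instances
        if e.etype is EdgeType.PPI:
            heads = [(e.a.key, e.b.key), (e.b.key, e.a.key)]
        else:
            heads = [(e.a.key, e.b.key)]
        for tail, head in heads:
            arcs.append(Arc(tail, head, edge_capacity, cost, e))
            if head in overlap:
                arcs.append(Arc(tail, head + ("target_copy",), edge_capacity, cost, e))
    for k in overlap:
        copy_of[k + ("target_copy",)] = k

    src_of_key = {v: k for k, v in src_keys.items()}
    for ident, key in src_keys.items():
        arcs.append(Arc(S_KEY, key, sw[ident], 0.0, None))
    for ident, key in tgt_keys.items():
        tkey = key + ("target_copy",) if key in overlap else key
        arcs.append(Arc(tkey, T_KEY, tw[ident], 0.0, None))

    return FlowProblem(arcs=arcs, gamma=gamma, source_weights={src_keys[i]: w for i, w in sw.items()},
                       target_weights={tgt_keys[i]: w for i, w in tw.items()},
                       not_connectable=not_conn, copy_of=copy_of, net=net)


# ---------------------------------------------------------------------------
# solving
# ---------------------------------------------------------------------------

def solve_flow(p: FlowProblem) -> FlowSolution:
    """Solve the LP and cancel antiparallel PPI flows.

    Cancelling min(f_ab, f_ba) from both directions of a PPI never increases
    the objective (arc costs are >= 0) and restores a physically interpretable
    flow; it matters only for zero-cost arcs, where antiparallel optima are
    not excluded by optimality alone.
    """
    arcs = p.arcs
    n_arcs = len(arcs)
    node_index: dict[tuple, int] = {}
    for a in arcs:
        for k in (a.tail, a.head):
            if k not in (S_KEY, T_KEY) and k not in node_index:
                node_index[k] = len(node_index)
    rows, cols, vals = [], [], []
    for j, a in enumerate(arcs):
        if a.tail in node_index:
            rows.append(node_index[a.tail]); cols.append(j); vals.append(-1.0)
        if a.head in node_index:
            rows.append(node_index[a.head]); cols.append(j); vals.append(1.0)
    A_eq = coo_matrix((vals, (rows, cols)), shape=(len(node_index), n_arcs))
    c = np.array([a.cost - (p.gamma if a.tail == S_KEY else 0.0) for a in arcs])
    bounds = [(0.0, a.capacity) for a in arcs]
    res = linprog(c, A_eq=A_eq.tocsr(), b_eq=np.zeros(len(node_index)),
                  bounds=bounds, method="highs")
    if res.status != 0:
        raise SolverError(status=res.message)
    flows = np.asarray(res.x, dtype=float)
    flows[np.abs(flows) < 1e-12] = 0.0

    # antiparallel cancellation per PPI interaction
    ppi_dirs: dict[tuple, dict[tuple, int]] = {}
    for j, a in enumerate(arcs):
        if a.interaction is not None and a.interaction.etype is EdgeType.PPI:
            # exclude target-copy clones: they are not antiparallel pairs
            if len(a.tail) == 2 and len(a.head) == 2:
                ppi_dirs.setdefault(a.interaction.key, {})[(a.tail, a.head)] = j
    for dirs in ppi_dirs.values():
        if len(dirs) == 2:
            j1, j2 = dirs.values()
            cancel = min(flows[j1], flows[j2])
            if cancel > 0:
                flows[j1] -= cancel
                flows[j2] -= cancel
    return FlowSolution(flows=flows, objective=float(res.fun), status="optimal")


def check_conservation(p: FlowProblem, sol: FlowSolution, tol: float = 1e-8) -> float:
    """Max absolute node imbalance over interior nodes; raises above tol."""
    balance: dict[tuple, float] = {}
    for a, f in zip(p.arcs, sol.flows):
        balance[a.tail] = balance.get(a.tail, 0.0) - f
        balance[a.head] = balance.get(a.head, 0.0) + f
    worst = 0.0
    for k, v in balance.items():
        if k in (S_KEY, T_KEY):
            continue
        worst = max(worst, abs(v))
    if worst > tol:
        raise SolverError(status="imbalance", message=f"conservation violated: {worst}")
    return worst


# ---------------------------------------------------------------------------
# extraction
# ---------------------------------------------------------------------------

def extract_subnetwork(sol: FlowSolution, p: FlowProblem, eps: float = 1e-6,
                       name: str = "subnetwork") -> Subnetwork:
    """Keep arcs with flow > eps, map back to interactions, classify nodes."""
    edge_flow: dict[tuple, tuple[Interaction, float]] = {}
    throughput: dict[NodeKey, float] = {}
    connected_sources: list[str] = []
    connected_targets: list[str] = []

    def orig(key: tuple) -> NodeKey:
        return p.copy_of.get(key, key)  # type: ignore[arg-type]

    for a, f in zip(p.arcs, sol.flows):
        if f <= eps:
            continue
        if a.tail == S_KEY:
            connected_sources.append(a.head[0])
            continue
        if a.head == T_KEY:
            connected_targets.append(orig(a.tail)[0])
            continue
        inter = a.interaction
        assert inter is not None
        prev = edge_flow.get(inter.key)
        edge_flow[inter.key] = (inter, f + (prev[1] if prev else 0.0))
        throughput[orig(a.head)] = throughput.get(orig(a.head), 0.0) + f

    roles: dict[NodeKey, str] = {}
    present: set[NodeKey] = set()
    for inter, _f in edge_flow.values():
        present.add(inter.a.key)
        present.add(inter.b.key)
    tgt_orig = {orig(k) if len(k) > 2 else k for k in p.target_weights}
    for k in present:
        if k in p.source_weights:
            roles[k] = "source"
        elif k in p.target_weights or k in tgt_orig:
            roles[k] = "target"
        else:
            roles[k] = "connecting"

    sub = Subnetwork(
        name=name,
        edges=sorted(edge_flow.values(), key=lambda ef: ef[0].key),
        node_roles=roles,
        node_throughput=throughput,
        connected_sources=sorted(set(connected_sources)),
        connected_targets=sorted(set(connected_targets)),
        config={"gamma": p.gamma, "eps": eps, "solver": sol.solver,
                "build_tag": p.net.build_tag if p.net is not None else "",
                "not_connectable": p.not_connectable},
    )
    if p.net is not None:
        sub.annotations = {i: a for i, a in p.net.annotations.items()
                           if any(m.id == i for m in sub.nodes)}
    return sub


def run_responsenet(net: Interactome, sources: Sequence[str], targets: Sequence[str],
                    gamma: float = 10.0, eps: float = 1e-6,
                    source_weights: Optional[Mapping[str, float]] = None,
                    target_weights: Optional[Mapping[str, float]] = None,
                    name: str = "subnetwork") -> Subnetwork:
    """Convenience wrapper: build, solve, verify conservation, extract."""
    p = build_flow_problem(net, sources, targets, gamma=gamma,
                           source_weights=source_weights, target_weights=target_weights)
    sol = solve_flow(p)
    check_conservation(p, sol)
    return extract_subnetwork(sol, p, eps=eps, name=name)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def subnetwork_to_dict(sub: Subnetwork) -> dict:
    """JSON-ready representation (also the layers-module exchange format)."""
    nodes = []
    for m in sorted(sub.nodes):
        entry = {"id": m.id, "kind": m.kind.value,
                 "role": sub.node_roles.get(m.key, "connecting"),
                 "throughput": sub.node_throughput.get(m.key, 0.0)}
        ann = sub.annotations.get(m.id)
        if ann is not None:
            entry["annotation"] = {"diseases": ann.diseases,
                                   "drug_targets": ann.drug_targets,
                                   "variability": ann.variability}
        nodes.append(entry)
    edges = [{"a_id": e.a.id, "a_kind": e.a.kind.value,
              "b_id": e.b.id, "b_kind": e.b.kind.value,
              "etype": e.etype.value, "weight": e.weight, "flow": f,
              "provenance": e.provenance}
             for e, f in sub.edges]
    return {"name": sub.name, "config": sub.config,
            "connected_sources": sub.connected_sources,
            "connected_targets": sub.connected_targets,
            "nodes": nodes, "edges": edges}


def subnetwork_from_dict(d: dict) -> Subnetwork:
    edges = []
    for row in d["edges"]:
        inter = Interaction(Molecule(row["a_id"], Kind(row["a_kind"])),
                            Molecule(row["b_id"], Kind(row["b_kind"])),
                            EdgeType(row["etype"]), row["weight"],
                            provenance=row.get("provenance", ""))
        edges.append((inter, float(row["flow"])))
    roles = {(n["id"], n["kind"]): n["role"] for n in d["nodes"]}
    throughput = {(n["id"], n["kind"]): float(n.get("throughput", 0.0))
                  for n in d["nodes"]}
    return Subnetwork(name=d.get("name", "subnetwork"), edges=edges,
                      node_roles=roles, node_throughput=throughput,
                      connected_sources=list(d.get("connected_sources", [])),
                      connected_targets=list(d.get("connected_targets", [])),
                      config=dict(d.get("config", {})))


def write_subnetwork_json(sub: Subnetwork, path) -> None:
    import json
    from pathlib import Path
    Path(path).write_text(json.dumps(subnetwork_to_dict(sub), indent=1,
                                     sort_keys=True) + "\n")


def read_subnetwork_json(path) -> Subnetwork:
    import json
    from pathlib import Path
    return subnetwork_from_dict(json.loads(Path(path).read_text()))


def write_subnetwork_tsv(sub: Subnetwork, path) -> None:
    """Edge table: interactome dialect plus flow and endpoint-role columns."""
    cols = ["a_id", "a_kind", "b_id", "b_kind", "etype", "weight", "flow",
            "a_role", "b_role"]
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("\t".join(cols) + "\n")
        for e, f in sub.edges:
            fh.write("\t".join([
                e.a.id, e.a.kind.value, e.b.id, e.b.kind.value, e.etype.value,
                f"{e.weight:.10g}", f"{f:.10g}",
                sub.node_roles.get(e.a.key, "connecting"),
                sub.node_roles.get(e.b.key, "connecting"),
            ]) + "\n")


# ---------------------------------------------------------------------------
# empirical node significance
# ---------------------------------------------------------------------------

def _degree_bins(net: Interactome, n_bins: int = 10) -> dict[NodeKey, int]:
    """Assign each node a degree-decile bin (0..n_bins-1)."""
    deg: dict[NodeKey, int] = {m.key: 0 for m in net.nodes}
    for e in net.edges:
        deg[e.a.key] += 1
        deg[e.b.key] += 1
    keys = sorted(deg, key=lambda k: (deg[k], k))
    bins: dict[NodeKey, int] = {}
    n = len(keys)
    for rank, k in enumerate(keys):
        bins[k] = min(n_bins - 1, rank * n_bins // max(n, 1))
    return bins


def _sample_matched(rng: np.random.Generator, net: Interactome,
                    originals: Sequence[NodeKey], kinds: tuple[Kind, ...],
                    bins: dict[NodeKey, int]) -> list[str]:
    """Degree-matched random ids: for each original, sample a node of an
    admissible kind within +-1 degree-decile bin; uniform fallback if the
    candidate pool is too small."""
    pool = [m.key for m in net.nodes if Kind(m.key[1]) in kinds]
    chosen: list[str] = []
    taken: set[NodeKey] = set()
    for k in originals:
        b = bins.get(k, 0)
        cands = [c for c in pool if abs(bins[c] - b) <= 1 and c not in taken]
        if not cands:
            cands = [c for c in pool if c not in taken]
            if not cands:
                cands = pool
            logger.warning("insufficient degree-matched candidates; uniform fallback")
        pick = cands[int(rng.integers(len(cands)))]
        taken.add(pick)
        chosen.append(pick[0])
    return chosen


def node_significance(net: Interactome, sources: Sequence[str],
                      targets: Sequence[str], n_rand: int, seed: int,
                      gamma: float = 10.0, eps: float = 1e-6) -> dict[NodeKey, float]:
    """Empirical per-node p-values for the real subnetwork's nodes.

    The full run is repeated ``n_rand`` times with source/target sets replaced
    by degree-matched random sets (sampled within +-1 degree-decile bins);
    p(node) = (1 + #random runs whose subnetwork contains node) / (1 + n_rand).
    """
    if n_rand < 1:
        raise ValidationError("n_rand must be >= 1")
    real = run_responsenet(net, sources, targets, gamma=gamma, eps=eps)
    real_nodes = real.node_keys
    if not real_nodes:
        return {}
    rng = np.random.default_rng(seed)
    bins = _degree_bins(net)
    src_keys = [(s, Kind.PROTEIN.value) for s in sources
                if net.has_node((s, Kind.PROTEIN.value))]
    tgt_keys = []
    for t in targets:
        for k in (Kind.GENE, Kind.PROTEIN, Kind.MIRNA):
            if net.has_node((t, k.value)):
                tgt_keys.append((t, k.value))
                break
    hits = {k: 0 for k in real_nodes}
    for _ in range(n_rand):
        rs = _sample_matched(rng, net, src_keys, (Kind.PROTEIN,), bins)
        rt = _sample_matched(rng, net, tgt_keys, (Kind.GENE, Kind.PROTEIN, Kind.MIRNA), bins)
        try:
            rand_sub = run_responsenet(net, rs, rt, gamma=gamma, eps=eps)
        except ValidationError:
            continue
        rand_nodes = rand_sub.node_keys
        for k in real_nodes:
            if k in rand_nodes:
                hits[k] += 1
    return {k: (1 + h) / (1 + n_rand) for k, h in sorted(hits.items())}
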