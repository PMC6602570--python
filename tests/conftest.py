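from __future__ import annotations

import sys
from pathlib import Path

import networkx as nx
import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for `import oracles`

from respnet.interactome import (EdgeType, Interaction, Interactome, Kind,
                                 Molecule, REGULATORY_ETYPES)


def P(i: str) -> Molecule:
    return Molecule(i, Kind.PROTEIN)


def G(i: str) -> Molecule:
    return Molecule(i, Kind.GENE)


def M(i: str) -> Molecule:
    return Molecule(i, Kind.MIRNA)


def ppi(a: str, b: str, w: float) -> Interaction:
    return Interaction(P(a), P(b), EdgeType.PPI, w)


def tfdna(a: str, b: str, w: float = 1.0) -> Interaction:
    return Interaction(P(a), G(b), EdgeType.TF_DNA, w)


def build_net(*interactions: Interaction, build_tag: str = "test") -> Interactome:
    net = Interactome(build_tag=build_tag)
    for e in interactions:
        net.add_interaction(e)
    net.validate()
    return net


def random_typed_graph(rng: np.random.Generator, max_nodes: int = 8,
                       require_path: bool = True):
    """Small random typed interactome + source/target sets.

    At most ``max_nodes`` molecules; PPIs with random weights plus weight-1
    TF->gene edges; sources are proteins, targets genes.  Resamples until a
    source-to-target path exists when ``require_path``.
    """
    for _ in range(200):
        n_prot = int(rng.integers(3, max_nodes - 1))
        n_gene = int(rng.integers(1, max_nodes - n_prot + 1))
        prots = [f"P{i}" for i in range(n_prot)]
        genes = [f"G{i}" for i in range(n_gene)]
        net = Interactome(build_tag="rand")
        for i in range(n_prot):
            for j in range(i + 1, n_prot):
                if rng.random() < 0.45:
                    net.add_interaction(ppi(prots[i], prots[j],
                                            float(rng.uniform(0.2, 0.95))))
        for p in prots:
            for g in genes:
                if rng.random() < 0.35:
                    net.add_interaction(tfdna(p, g))
        present_p = [p for p in prots if net.has_node((p, Kind.PROTEIN.value))]
        present_g = [g for g in genes if net.has_node((g, Kind.GENE.value))]
        if not present_p or not present_g:
            continue
        n_src = min(len(present_p), int(rng.integers(1, 3)))
        sources = list(rng.choice(present_p, size=n_src, replace=False))
        targets = list(rng.choice(present_g,
                                  size=min(len(present_g), int(rng.integers(1, 3))),
                                  replace=False))
        if not require_path:
            return net, sources, targets
        H = nx.DiGraph()
        for e in net.edges:
            H.add_edge(e.a.key, e.b.key)
            if e.etype is EdgeType.PPI:
                H.add_edge(e.b.key, e.a.key)
        ok = any(
            H.has_node((s, "PROTEIN")) and H.has_node((t, "GENE"))
            and nx.has_path(H, (s, "PROTEIN"), (t, "GENE"))
            for s in sources for t in targets)
        if ok:
            return net, sources, targets
    raise RuntimeError("could not generate a connected instance")


def assert_regulatory_terminal(sub) -> None:
    """Every source -> GENE-target simple path must be PPIs followed by a
    single terminal regulatory step (TF->gene, or TF->microRNA->gene)."""
    H = nx.DiGraph()
    for e, _f in sub.edges:
        H.add_edge(e.a.key, e.b.key, etype=e.etype)
        if e.etype is EdgeType.PPI:
            H.add_edge(e.b.key, e.a.key, etype=e.etype)
    srcs = [k for k, r in sub.node_roles.items() if r == "source"]
    gene_tgts = [k for k, r in sub.node_roles.items()
                 if r == "target" and k[1] == Kind.GENE.value]
    for s in srcs:
        for t in gene_tgts:
            if not (H.has_node(s) and H.has_node(t)):
                continue
            for path in nx.all_simple_paths(H, s, t):
                etypes = [H[u][v]["etype"] for u, v in zip(path[:-1], path[1:])]
                reg_idx = [i for i, et in enumerate(etypes)
                           if et in REGULATORY_ETYPES]
                assert reg_idx, f"path {path} has no regulatory edge"
                first = reg_idx[0]
                assert all(et is EdgeType.PPI for et in etypes[:first]), \
                    f"non-PPI before regulatory step in {path}"
                assert reg_idx == list(range(first, len(etypes))), \
                    f"PPI after regulatory step in {path}"
                assert etypes[-1] in (EdgeType.TF_DNA, EdgeType.MIRNA_RNA)
                assert len(reg_idx) <= 2


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
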