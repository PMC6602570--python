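"""Synthetic benchmark generators with known ground truth.

Two generators: (1) interactomes with planted high-weight source-to-gene
pathways buried in low-weight noise PPIs, for exercising the flow solver; and
(2) GTEx-like raw count matrices with per-tissue planted expressed gene sets,
negative-binomial counts and log-uniform library sizes, for exercising the
TMM/expression pipeline.  All outputs are deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .expression import CountMatrix
from .interactome import (EdgeType, Interaction, Interactome, Kind, Molecule)

__all__ = ["PlantedTruth", "make_planted_interactome", "make_counts"]


@dataclass
class PlantedTruth:
    """Ground truth bundled with a synthetic instance."""

    planted_paths: list[list[tuple]] = field(default_factory=list)  # edge keys per path
    noise_edges: set = field(default_factory=set)                   # edge keys
    expressed_truth: dict[str, frozenset] = field(default_factory=dict)
    seed: int = 0

    @property
    def planted_edges(self) -> set:
        return {k for path in self.planted_paths for k in path}


def make_planted_interactome(
    n_proteins: int = 60,
    n_genes: int = 10,
    n_mirnas: int = 0,
    n_paths: int = 3,
    path_len: int = 4,
    w_planted: float = 0.9,
    w_noise: float = 0.2,
    noise_density: float = 0.1,
    seed: int = 0,
) -> tuple[Interactome, list[str], list[str], PlantedTruth]:
    """Plant ``n_paths`` disjoint high-weight pathways among Erdos-Renyi noise.

    Each planted path is ``path_len`` edges: a source protein, a chain of
    ``path_len - 1`` PPIs through fresh intermediate proteins ending at a TF,
    then one regulatory edge to a dedicated gene target (TF_DNA) or, when
    microRNAs are requested, TF -> microRNA -> gene for some paths.  Noise PPIs
    at weight ``w_noise`` are drawn between protein pairs not on any planted
    edge.  Returns (interactome, source ids, target ids, truth).
    """
    if path_len < 2:
        raise ValidationError("path_len must be >= 2")
    if n_paths * path_len > n_proteins:
        raise ValidationError(
            f"need >= {n_paths * path_len} proteins for {n_paths} disjoint "
            f"paths of length {path_len}, got {n_proteins}")
    if n_paths > n_genes:
        raise ValidationError("need one gene target per planted path")
    rng = np.random.default_rng(seed)

    proteins = [f"P{i:04d}" for i in range(n_proteins)]
    genes = [f"G{i:04d}" for i in range(n_genes)]
    mirnas = [f"miR-{i:03d}" for i in range(n_mirnas)]
    net = Interactome(build_tag=f"synth-planted(seed={seed})")
    for pid in proteins:
        net.add_node(Molecule(pid, Kind.PROTEIN))
    for gid in genes:
        net.add_node(Molecule(gid, Kind.GENE))
    for mid in mirnas:
        net.add_node(Molecule(mid, Kind.MIRNA))

    truth = PlantedTruth(seed=seed)
    sources: list[str] = []
    targets: list[str] = []
    # planted paths occupy a disjoint prefix of the protein list
    n_ppi_hops = path_len - 1
    use_mirna_for = set(range(n_paths)) if False else set()
    if n_mirnas:
        use_mirna_for = set(range(min(n_mirnas, n_paths)))
    for i in range(n_paths):
        chain = proteins[i * path_len:(i + 1) * path_len][: n_ppi_hops + 1]
        path_keys: list[tuple] = []
        for u, v in zip(chain[:-1], chain[1:]):
            e = Interaction(Molecule(u, Kind.PROTEIN), Molecule(v, Kind.PROTEIN),
                            EdgeType.PPI, w_planted, provenance="planted")
            net.add_interaction(e)
            path_keys.append(e.key)
        tf = chain[-1]
        gene = genes[i]
        if i in use_mirna_for:
            mir = mirnas[i]
            e1 = Interaction(Molecule(tf, Kind.PROTEIN), Molecule(mir, Kind.MIRNA),
                             EdgeType.TF_MIRNA, 1.0, provenance="planted")
            e2 = Interaction(Molecule(mir, Kind.MIRNA), Molecule(gene, Kind.GENE),
                             EdgeType.MIRNA_RNA, 1.0, provenance="planted")
            net.add_interaction(e1)
            net.add_interaction(e2)
            path_keys.extend([e1.key, e2.key])
        else:
            e = Interaction(Molecule(tf, Kind.PROTEIN), Molecule(gene, Kind.GENE),
                            EdgeType.TF_DNA, 1.0, provenance="planted")
            net.add_interaction(e)
            path_keys.append(e.key)
        truth.planted_paths.append(path_keys)
        sources.append(chain[0])
        targets.append(gene)

    planted = truth.planted_edges
    # Erdos-Renyi noise PPIs over all protein pairs, skipping planted edges
    n_pairs = n_proteins * (n_proteins - 1) // 2
    n_noise = int(round(noise_density * n_pairs)) if noise_density <= 1 else int(noise_density)
    pairs = rng.choice(n_pairs, size=min(n_noise, n_pairs), replace=False)
    idx_u = np.triu_indices(n_proteins, k=1)
    for flat in sorted(pairs):
        u, v = proteins[idx_u[0][flat]], proteins[idx_u[1][flat]]
        e = Interaction(Molecule(u, Kind.PROTEIN), Molecule(v, Kind.PROTEIN),
                        EdgeType.PPI, w_noise, provenance="noise")
        if e.key in planted:
            continue
        net.add_interaction(e)
        truth.noise_edges.add(e.key)
    net.validate()
    return net, sources, targets, truth


def make_counts(
    genes: Sequence[str] | int = 200,
    tissues: Sequence[str] = ("tissueA", "tissueB"),
    samples_per_tissue: int = 15,
    expressed_frac: float = 0.4,
    mean_expressed_cpm: float = 50.0,
    mean_silent_cpm: float = 0.5,
    libsize_range: tuple[float, float] = (5e5, 2e6),
    dispersion: float = 0.1,
    n_housekeeping: int = 50,
    seed: int = 0,
) -> tuple[CountMatrix, PlantedTruth]:
    """Negative-binomial count matrix with planted per-tissue expressed sets.

    Per tissue, a fraction ``expressed_frac`` of genes is drawn as expressed at
    a nominal ``mean_expressed_cpm``; the rest sit at ``mean_silent_cpm``.
    ``n_housekeeping`` filler genes, expressed in every tissue, absorb the
    remaining per-million mass so that nominal cpm values are realized (counts
    must sum to the library size).  Library sizes are log-uniform over
    ``libsize_range``; counts are NB with the given dispersion (Poisson in the
    limit dispersion -> 0).
    """
    if libsize_range[0] <= 0 or libsize_range[1] < libsize_range[0]:
        raise ValidationError("libsize_range must be positive and ordered")
    if not 0 <= expressed_frac <= 1:
        raise ValidationError("expressed_frac must be in [0, 1]")
    if n_housekeeping < 1:
        raise ValidationError("n_housekeeping must be >= 1")
    rng = np.random.default_rng(seed)
    gene_ids = [f"ENSG{i:08d}" for i in range(genes)] if isinstance(genes, int) else list(genes)
    hk_ids = [f"ENSGHK{i:06d}" for i in range(n_housekeeping)]
    n_genes = len(gene_ids)
    budget = 1e6 - n_genes * mean_expressed_cpm
    if budget <= 0:
        raise ValidationError("mean_expressed_cpm too large for gene count")
    hk_cpm = budget / n_housekeeping

    sample_ids: list[str] = []
    tissue_of: dict[str, str] = {}
    cols: list[np.ndarray] = []
    truth = PlantedTruth(seed=seed)
    all_ids = np.array(gene_ids + hk_ids)
    for tissue in tissues:
        n_expr = int(round(expressed_frac * n_genes))
        expr_idx = rng.choice(n_genes, size=n_expr, replace=False)
        mask = np.zeros(n_genes + n_housekeeping, dtype=bool)
        mask[expr_idx] = True
        mask[n_genes:] = True  # housekeeping expressed everywhere
        truth.expressed_truth[tissue] = frozenset(all_ids[mask])
        nominal_cpm = np.where(mask, mean_expressed_cpm, mean_silent_cpm)
        nominal_cpm[n_genes:] = hk_cpm
        for j in range(samples_per_tissue):
            sid = f"{tissue}_s{j:03d}"
            sample_ids.append(sid)
            tissue_of[sid] = tissue
            lib = np.exp(rng.uniform(np.log(libsize_range[0]), np.log(libsize_range[1])))
            mu = nominal_cpm * lib / 1e6
            if dispersion <= 0:
                counts = rng.poisson(mu)
            else:
                # NB via gamma-Poisson mixture, var = mu + dispersion * mu^2
                shape = 1.0 / dispersion
                lam = rng.gamma(shape, mu / shape)
                counts = rng.poisson(lam)
            cols.append(counts.astype(np.int64))

    df = pd.DataFrame(np.column_stack(cols), index=list(all_ids), columns=sample_ids)
    return CountMatrix(counts=df, tissue_of=tissue_of), truth
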