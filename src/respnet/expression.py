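"""Tissue-specific interactome construction from raw RNA-seq counts.

Pipeline: prefilter lowly covered genes, TMM-normalize library sizes to
counts-per-million (cpm), call per-tissue expressed genes from median cpm,
then restrict the global interactome so each retained PPI has both partners
expressed in the tissue.  Regulatory and microRNA edges are exempt from
expression filtering.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import ValidationError
from .interactome import EdgeType, Interactome, Kind

logger = logging.getLogger(__name__)

__all__ = [
    "CountMatrix",
    "CpmMatrix",
    "ExpressionCall",
    "read_counts_tsv",
    "read_tissue_map",
    "prefilter_counts",
    "tmm_normalize",
    "call_expressed",
    "build_tissue_interactome",
]


@dataclass
class CountMatrix:
    """Raw read counts, genes x samples, with a sample -> tissue map."""

    counts: pd.DataFrame
    tissue_of: dict[str, str]

    def __post_init__(self) -> None:
        vals = self.counts.to_numpy()
        if vals.size and (vals < 0).any():
            raise ValidationError("negative counts")
        if vals.size and not np.allclose(vals, np.round(vals)):
            raise ValidationError("counts must be integral")
        missing = [s for s in self.counts.columns if s not in self.tissue_of]
        if missing:
            raise ValidationError(f"samples without tissue label: {missing[:5]}")

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def tissues(self) -> list[str]:
        return sorted({self.tissue_of[s] for s in self.samples})

    def samples_of(self, tissue: str) -> list[str]:
        out = [s for s in self.samples if self.tissue_of[s] == tissue]
        if not out:
            raise KeyError(f"unknown tissue {tissue!r}")
        return out


@dataclass
class CpmMatrix:
    """TMM-normalized counts per million with the per-sample factors used."""

    cpm: pd.DataFrame
    norm_factors: pd.Series
    tissue_of: dict[str, str]

    @property
    def genes(self) -> list[str]:
        return list(self.cpm.index)

    @property
    def samples(self) -> list[str]:
        return list(self.cpm.columns)

    def samples_of(self, tissue: str) -> list[str]:
        out = [s for s in self.samples if self.tissue_of[s] == tissue]
        if not out:
            raise KeyError(f"unknown tissue {tissue!r}")
        return out


@dataclass
class ExpressionCall:
    """The set of genes called expressed in one tissue, plus the thresholds used."""

    tissue: str
    expressed: frozenset[str]
    threshold_config: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_counts_tsv(counts_path: Union[str, Path],
                    tissues_path: Union[str, Path]) -> CountMatrix:
    """Counts TSV (first column gene_id, then sample columns) + 2-column
    sample/tissue TSV."""
    df = pd.read_csv(counts_path, sep="\t", index_col=0)
    tissue_of = read_tissue_map(tissues_path)
    return CountMatrix(counts=df, tissue_of=tissue_of)


def read_tissue_map(path: Union[str, Path]) -> dict[str, str]:
    tm = pd.read_csv(path, sep="\t", header=None, names=["sample", "tissue"],
                     dtype=str, comment="#")
    return dict(zip(tm["sample"], tm["tissue"]))


def write_counts_tsv(cm: CountMatrix, counts_path: Union[str, Path],
                     tissues_path: Union[str, Path]) -> None:
    cm.counts.to_csv(counts_path, sep="\t", index_label="gene_id")
    with open(tissues_path, "wt", encoding="utf-8") as fh:
        for s in cm.samples:
            fh.write(f"{s}\t{cm.tissue_of[s]}\n")


# ---------------------------------------------------------------------------
# filtering and normalization
# ---------------------------------------------------------------------------

def prefilter_counts(cm: CountMatrix, min_count: int = 5,
                     min_samples: int = 10) -> CountMatrix:
    """Keep genes with more than ``min_count`` reads in at least ``min_samples``
    samples (strict inequality on counts)."""
    if min_count < 0 or min_samples < 0:
        raise ValidationError("prefilter parameters must be >= 0")
    if min_samples > len(cm.samples):
        logger.warning("min_samples=%d exceeds sample count %d; result may be empty",
                       min_samples, len(cm.samples))
    hits = (cm.counts.to_numpy() > min_count).sum(axis=1)
    keep = hits >= min_samples
    return CountMatrix(counts=cm.counts.loc[keep], tissue_of=cm.tissue_of)


def _quantile_r7(x: np.ndarray, p: float) -> float:
    # R's default quantile (type 7) == numpy linear interpolation
    return float(np.quantile(x, p, method="linear"))


def _tmm_factor(obs: np.ndarray, ref: np.ndarray, trim_M: float, trim_A: float) -> float:
    """One sample's TMM factor against the reference (edgeR-style)."""
    n_obs = obs.sum()
    n_ref = ref.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        p_obs = obs / n_obs
        p_ref = ref / n_ref
        M = np.log2(p_obs / p_ref)
        A = 0.5 * (np.log2(p_obs) + np.log2(p_ref))
        # asymptotic variance of M under binomial sampling
        v = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    finite = np.isfinite(M) & np.isfinite(A)
    M, A, v = M[finite], A[finite], v[finite]
    if M.size == 0:
        logger.warning("sample shares no nonzero gene with reference; factor set to 1")
        return 1.0
    if np.max(np.abs(M)) < 1e-6:
        return 1.0
    n = M.size
    lo_M = math.floor(n * trim_M) + 1
    hi_M = n + 1 - lo_M
    lo_A = math.floor(n * trim_A) + 1
    hi_A = n + 1 - lo_A
    rM = rankdata(M)
    rA = rankdata(A)
    keep = (rM >= lo_M) & (rM <= hi_M) & (rA >= lo_A) & (rA <= hi_A)
    if not keep.any():
        return 1.0
    f = np.sum(M[keep] / v[keep]) / np.sum(1.0 / v[keep])
    return float(2.0 ** f)


def tmm_normalize(cm: CountMatrix, trim_M: float = 0.30,
                  trim_A: float = 0.05) -> CpmMatrix:
    """Trimmed-mean-of-M-values normalization to counts per million.

    Reference sample: the one whose upper quartile of library-scaled counts is
    closest to the mean upper quartile.  Per-sample factor: 2^(inverse-variance
    weighted mean of log2 expression ratios vs the reference), after dropping
    genes with a zero in either sample and trimming the extreme ``trim_M``
    fraction of M-values and ``trim_A`` fraction of A-values on each side.
    Factors are rescaled to geometric mean 1; cpm = count / (library size x
    factor) x 1e6.
    """
    X = cm.counts.to_numpy(dtype=float)
    n_genes, n_samples = X.shape
    if n_samples < 2:
        raise ValidationError("TMM needs at least 2 samples")
    lib = X.sum(axis=0)
    if (lib == 0).any():
        raise ValidationError("all-zero sample(s) present")
    uq = np.array([_quantile_r7(X[:, j] / lib[j], 0.75) for j in range(n_samples)])
    ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    ref = X[:, ref_idx]
    factors = np.array([
        1.0 if j == ref_idx else _tmm_factor(X[:, j], ref, trim_M, trim_A)
        for j in range(n_samples)
    ])
    factors = factors / np.exp(np.mean(np.log(factors)))
    cpm = X / (lib * factors)[None, :] * 1e6
    return CpmMatrix(
        cpm=pd.DataFrame(cpm, index=cm.counts.index, columns=cm.counts.columns),
        norm_factors=pd.Series(factors, index=cm.counts.columns, name="norm_factor"),
        tissue_of=cm.tissue_of,
    )


def call_expressed(cpmM: CpmMatrix, tissue: str, cpm_threshold: float = 8.0,
                   min_samples: int = 10, median_threshold: float = 8.0,
                   median_scale: str = "cpm",
                   stage1_scope: str = "tissue") -> ExpressionCall:
    """Two-stage expressed-gene call for one tissue.

    Stage 1 keeps genes with cpm >= ``cpm_threshold`` in at least
    ``min_samples`` samples (within the tissue by default;
    ``stage1_scope='all'`` counts across all samples).  Stage 2 merges the
    tissue's samples by the per-gene median cpm and keeps genes whose median
    passes ``median_threshold``.  With ``median_scale='log2cpm'`` the stage-2
    comparison is log2(median cpm) >= threshold instead.
    """
    if median_scale not in ("cpm", "log2cpm"):
        raise ValueError("median_scale must be 'cpm' or 'log2cpm'")
    if stage1_scope not in ("tissue", "all"):
        raise ValueError("stage1_scope must be 'tissue' or 'all'")
    tissue_samples = cpmM.samples_of(tissue)  # raises KeyError if unknown
    sub = cpmM.cpm[tissue_samples]
    stage1_frame = cpmM.cpm if stage1_scope == "all" else sub
    n_pass = (stage1_frame.to_numpy() >= cpm_threshold).sum(axis=1)
    stage1 = pd.Series(n_pass >= min_samples, index=cpmM.cpm.index)
    medians = sub.median(axis=1)
    if median_scale == "log2cpm":
        with np.errstate(divide="ignore"):
            stage2 = np.log2(medians.to_numpy()) >= median_threshold
    else:
        stage2 = medians.to_numpy() >= median_threshold
    expressed = frozenset(cpmM.cpm.index[stage1.to_numpy() & stage2])
    return ExpressionCall(
        tissue=tissue,
        expressed=expressed,
        threshold_config={
            "cpm_threshold": cpm_threshold,
            "min_samples": min_samples,
            "median_threshold": median_threshold,
            "median_scale": median_scale,
            "stage1_scope": stage1_scope,
        },
    )


def build_tissue_interactome(global_net: Interactome, call: ExpressionCall,
                             filter_tf: bool = False) -> Interactome:
    """Restrict the global interactome to one tissue.

    A PPI is kept iff both partner ids are in the expressed set.  Interactions
    involving microRNAs are never filtered.  TF->gene edges are kept by default
    (``filter_tf=True`` additionally requires the TF protein to be expressed).
    Nodes left without edges are dropped.
    """
    if not call.expressed:
        logger.warning("empty expressed set for tissue %r; only microRNA/regulatory "
                       "edges will remain", call.tissue)
    out = Interactome(build_tag=f"{global_net.build_tag}|tissue={call.tissue}|"
                                f"{call.threshold_config}")
    expressed = call.expressed
    for e in global_net.edges:
        if e.etype is EdgeType.PPI:
            if e.a.id in expressed and e.b.id in expressed:
                out.add_interaction(e)
        elif e.etype is EdgeType.TF_DNA and filter_tf:
            if e.a.id in expressed:
                out.add_interaction(e)
        else:
            out.add_interaction(e)
    out.drop_nodes_without_edges()
    out.annotations.update(global_net.annotations)
    out.validate()
    return out
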