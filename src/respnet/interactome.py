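"""Typed molecular-network data model with TSV/JSON I/O, merging and annotation.

Nodes are molecules keyed by ``(identifier, kind)`` so a gene and its protein
product are distinct nodes even when they share an identifier.  Edges are typed:
undirected protein-protein interactions (PPI) and three directed regulatory
layers (TF->gene, TF->microRNA, microRNA->gene transcript).  Gene-kind nodes are
pure regulatory sinks: no edge type allows a gene as a tail, so any path ending
at a gene necessarily ends with a single regulatory interaction.

Identifiers are taken verbatim (conventionally Ensembl gene IDs for
genes/proteins and miRBase-style names for microRNAs); identifier conversion is
a precondition, not a service of this package.
"""

from __future__ import annotations

import enum
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Optional, Sequence, Union

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "Kind",
    "EdgeType",
    "REGULATORY_ETYPES",
    "Molecule",
    "Interaction",
    "Interactome",
    "NodeAnnotation",
    "DefaultWeightPolicy",
    "ParseReport",
    "AnnotationReport",
    "parse_interaction_table",
    "write_interaction_table",
    "merge",
    "annotate",
    "logistic_weight",
]


class Kind(str, enum.Enum):
    """Molecule type."""

    PROTEIN = "PROTEIN"
    GENE = "GENE"
    MIRNA = "MIRNA"


class EdgeType(str, enum.Enum):
    """Interaction type; fixes endpoint kinds and directedness."""

    PPI = "PPI"
    TF_DNA = "TF_DNA"
    TF_MIRNA = "TF_MIRNA"
    MIRNA_RNA = "MIRNA_RNA"


#: (tail kind, head kind) admitted for each edge type.
ENDPOINT_KINDS: dict[EdgeType, tuple[Kind, Kind]] = {
    EdgeType.PPI: (Kind.PROTEIN, Kind.PROTEIN),
    EdgeType.TF_DNA: (Kind.PROTEIN, Kind.GENE),
    EdgeType.TF_MIRNA: (Kind.PROTEIN, Kind.MIRNA),
    EdgeType.MIRNA_RNA: (Kind.MIRNA, Kind.GENE),
}

REGULATORY_ETYPES = frozenset({EdgeType.TF_DNA, EdgeType.TF_MIRNA, EdgeType.MIRNA_RNA})

NodeKey = tuple[str, str]
EdgeKey = tuple[NodeKey, NodeKey, str]


@dataclass(frozen=True, order=True)
class Molecule:
    """A typed network node; ``(id, kind)`` is the unique key."""

    id: str
    kind: Kind

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("molecule id must be non-empty")
        if not isinstance(self.kind, Kind):
            raise ValidationError(f"invalid molecule kind: {self.kind!r}")

    @property
    def key(self) -> NodeKey:
        return (self.id, self.kind.value)


@dataclass(frozen=True)
class Interaction:
    """A typed weighted edge; PPIs are canonicalized to sorted endpoint order."""

    a: Molecule
    b: Molecule
    etype: EdgeType
    weight: float
    provenance: str = ""

    def __post_init__(self) -> None:
        if not isinstance(self.etype, EdgeType):
            raise ValidationError(f"invalid edge type: {self.etype!r}")
        ka, kb = ENDPOINT_KINDS[self.etype]
        if self.a.kind is not ka or self.b.kind is not kb:
            raise ValidationError(
                f"{self.etype.value} requires ({ka.value}, {kb.value}) endpoints, "
                f"got ({self.a.kind.value}, {self.b.kind.value}) for "
                f"{self.a.id}--{self.b.id}"
            )
        if self.a.key == self.b.key:
            raise ValidationError(f"self-loop on {self.a.key} not allowed")
        if not (isinstance(self.weight, (int, float)) and math.isfinite(self.weight)):
            raise ValidationError(f"non-finite weight on {self.a.id}--{self.b.id}")
        if not 0.0 < self.weight <= 1.0:
            raise ValidationError(
                f"weight {self.weight} outside (0, 1] on {self.a.id}--{self.b.id}"
            )
        if self.etype is EdgeType.PPI and self.b.key < self.a.key:
            # store undirected PPIs once, under sorted endpoint order
            a, b = self.a, self.b
            object.__setattr__(self, "a", b)
            object.__setattr__(self, "b", a)

    @property
    def directed(self) -> bool:
        return self.etype is not EdgeType.PPI

    @property
    def key(self) -> EdgeKey:
        return (self.a.key, self.b.key, self.etype.value)


@dataclass
class NodeAnnotation:
    """Optional per-node overlay: disease links, drug targets, variability score.

    ``variability`` is on a 0-100 scale: 0 for non-variable expression across
    individuals, 100 for maximum variability.
    """

    node_id: str
    diseases: list[str] = field(default_factory=list)
    drug_targets: list[str] = field(default_factory=list)
    variability: Optional[float] = None

    @property
    def maximal_variability(self) -> bool:
        return self.variability is not None and self.variability >= 100.0


class Interactome:
    """A validated collection of molecules and interactions.

    Duplicate edges (same endpoints and type) keep the maximum weight.
    """

    def __init__(self, build_tag: str = ""):
        self.build_tag = build_tag
        self._nodes: dict[NodeKey, Molecule] = {}
        self._edges: dict[EdgeKey, Interaction] = {}
        self.annotations: dict[str, NodeAnnotation] = {}

    # -- container protocol -------------------------------------------------

    def __len__(self) -> int:
        return len(self._edges)

    def __contains__(self, key: object) -> bool:
        return key in self._edges or key in self._nodes

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Interactome):
            return NotImplemented
        return self._nodes == other._nodes and self._edges == other._edges

    def __repr__(self) -> str:
        return (
            f"Interactome(nodes={self.n_nodes}, edges={self.n_edges}, "
            f"build_tag={self.build_tag!r})"
        )

    # -- accessors ----------------------------------------------------------

    @property
    def nodes(self) -> list[Molecule]:
        return list(self._nodes.values())

    @property
    def edges(self) -> list[Interaction]:
        return list(self._edges.values())

    @property
    def n_nodes(self) -> int:
        return len(self._nodes)

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    def node(self, key: NodeKey) -> Molecule:
        return self._nodes[key]

    def has_node(self, key: NodeKey) -> bool:
        return key in self._nodes

    def edges_of_type(self, etype: EdgeType) -> list[Interaction]:
        return [e for e in self._edges.values() if e.etype is etype]

    # -- construction -------------------------------------------------------

    def add_node(self, mol: Molecule) -> Molecule:
        return self._nodes.setdefault(mol.key, mol)

    def add_interaction(self, inter: Interaction) -> None:
        """Insert an edge; on duplicates, the maximum weight wins."""
        self.add_node(inter.a)
        self.add_node(inter.b)
        prev = self._edges.get(inter.key)
        if prev is None or inter.weight > prev.weight:
            self._edges[inter.key] = inter

    def drop_nodes_without_edges(self) -> int:
        used: set[NodeKey] = set()
        for e in self._edges.values():
            used.add(e.a.key)
            used.add(e.b.key)
        orphans = [k for k in self._nodes if k not in used]
        for k in orphans:
            del self._nodes[k]
        return len(orphans)

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        """Re-check all structural invariants; raises ValidationError."""
        for e in self._edges.values():
            if e.a.key not in self._nodes or e.b.key not in self._nodes:
                raise ValidationError(f"edge {e.key} has endpoint outside node set")
            if e.a.kind is Kind.GENE:
                raise ValidationError(f"GENE node {e.a.id} has an outgoing edge")
            if e.etype is EdgeType.PPI and e.b.key < e.a.key:
                raise ValidationError(f"PPI {e.key} not in canonical order")
        for ann in self.annotations.values():
            if ann.variability is not None and not 0.0 <= ann.variability <= 100.0:
                raise ValidationError(
                    f"variability {ann.variability} outside [0, 100] on {ann.node_id}"
                )

    # -- export -------------------------------------------------------------

    def sorted_edges(self) -> list[Interaction]:
        return sorted(self._edges.values(), key=lambda e: e.key)

    def to_elements(self) -> dict:
        """Graph-viewer (Cytoscape.js style) element arrays."""
        nodes = []
        for mol in sorted(self._nodes.values()):
            data = {"id": f"{mol.id}::{mol.kind.value}", "label": mol.id,
                    "kind": mol.kind.value}
            ann = self.annotations.get(mol.id)
            if ann is not None:
                if ann.diseases:
                    data["diseases"] = list(ann.diseases)
                if ann.drug_targets:
                    data["drug_targets"] = list(ann.drug_targets)
                if ann.variability is not None:
                    data["variability"] = ann.variability
            nodes.append({"data": data})
        edges = []
        for e in self.sorted_edges():
            edges.append({"data": {
                "source": f"{e.a.id}::{e.a.kind.value}",
                "target": f"{e.b.id}::{e.b.kind.value}",
                "etype": e.etype.value,
                "weight": e.weight,
            }})
        return {"nodes": nodes, "edges": edges}

    def write_json(self, path: Union[str, Path]) -> None:
        payload = {"build_tag": self.build_tag, "elements": self.to_elements()}
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# TSV dialect
# ---------------------------------------------------------------------------

HEADER = ["a_id", "a_kind", "b_id", "b_kind", "etype", "weight"]


def logistic_weight(n_publications: int, midpoint: float = 2.0, rate: float = 1.0) -> float:
    """Fallback PPI weight from supporting-publication count.

    A documented, explicitly non-canonical stand-in for externally supplied
    reliability weights: a logistic curve of the number of supporting
    publications, mapped into (0, 1].
    """
    if n_publications < 0:
        raise ValidationError("publication count must be >= 0")
    return 1.0 / (1.0 + math.exp(-rate * (n_publications - midpoint)))


@dataclass
class DefaultWeightPolicy:
    """How blank weight cells are filled.

    Regulatory edges (TF-DNA, TF-microRNA, microRNA-RNA) default to 1.0.
    Blank PPI weights are an error unless ``ppi`` provides a constant or a
    callable mapping the provenance string to a weight.
    """

    regulatory: float = 1.0
    ppi: Union[None, float, Callable[[str], float]] = None

    def fill(self, etype: EdgeType, provenance: str, row_no: int) -> float:
        if etype in REGULATORY_ETYPES:
            return self.regulatory
        if self.ppi is None:
            raise ValidationError(f"row {row_no}: blank weight on PPI with no default policy")
        if callable(self.ppi):
            return self.ppi(provenance)
        return float(self.ppi)


@dataclass
class ParseReport:
    n_rows: int = 0
    n_accepted: int = 0
    rejected: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)


def _parse_row(fields: Sequence[str], row_no: int, policy: DefaultWeightPolicy) -> Interaction:
    a_id, a_kind, b_id, b_kind, etype_s, weight_s = (f.strip() for f in fields[:6])
    provenance = fields[6].strip() if len(fields) > 6 else ""
    try:
        a_k = Kind(a_kind)
        b_k = Kind(b_kind)
    except ValueError as exc:
        raise ValidationError(f"row {row_no}: unknown kind: {exc}") from None
    try:
        etype = EdgeType(etype_s)
    except ValueError:
        raise ValidationError(f"row {row_no}: unknown etype {etype_s!r}") from None
    if weight_s == "":
        weight = policy.fill(etype, provenance, row_no)
    else:
        try:
            weight = float(weight_s)
        except ValueError:
            raise ValidationError(f"row {row_no}: unparseable weight {weight_s!r}") from None
    try:
        return Interaction(Molecule(a_id, a_k), Molecule(b_id, b_k), etype, weight,
                           provenance=provenance)
    except ValidationError as exc:
        raise ValidationError(f"row {row_no}: {exc}") from None


def parse_interaction_table(
    path: Union[str, Path],
    default_weight_policy: Optional[DefaultWeightPolicy] = None,
    on_invalid: str = "raise",
    build_tag: str = "",
) -> Interactome:
    """Read the interaction TSV dialect into a validated :class:`Interactome`.

    Columns: ``a_id  a_kind  b_id  b_kind  etype  weight`` (optional 7th
    ``provenance``).  Blank weights are filled by ``default_weight_policy``
    (regulatory edges -> 1.0).  Duplicate edges keep the maximum weight.

    ``on_invalid='raise'`` (default) aborts on the first bad row naming it;
    ``on_invalid='skip'`` drops bad rows and records them in the report
    attached as ``net.parse_report``.
    """
    if on_invalid not in ("raise", "skip"):
        raise ValueError("on_invalid must be 'raise' or 'skip'")
    policy = default_weight_policy or DefaultWeightPolicy()
    path = Path(path)
    net = Interactome(build_tag=build_tag or path.name)
    report = ParseReport()
    with open(path, "rt", encoding="utf-8") as fh:
        header_line = fh.readline()
        if not header_line:
            raise FormatError(f"{path}: empty file, expected header {HEADER}")
        header = [c.strip() for c in header_line.rstrip("\n").split("\t")]
        if header[: len(HEADER)] != HEADER:
            raise FormatError(f"{path}: bad header {header!r}, expected {HEADER}")
        for row_no, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 6:
                err: Exception = FormatError(f"row {row_no}: expected >= 6 columns")
            else:
                report.n_rows += 1
                try:
                    net.add_interaction(_parse_row(fields, row_no, policy))
                    report.n_accepted += 1
                    continue
                except ValidationError as exc:
                    err = exc
            if on_invalid == "raise":
                raise err
            report.rejected.append((row_no, str(err)))
            logger.warning("%s: rejected %s", path, err)
    net.parse_report = report  # type: ignore[attr-defined]
    if report.n_rejected:
        logger.info("%s: rejected %d/%d rows", path, report.n_rejected, report.n_rows)
    net.validate()
    return net


def _format_weight(w: float) -> str:
    return f"{w:.10g}"


def write_interaction_table(net: Interactome, path: Union[str, Path]) -> None:
    """Write the canonicalized table: sorted rows, PPIs in canonical order."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("\t".join(HEADER + ["provenance"]) + "\n")
        for e in net.sorted_edges():
            fh.write("\t".join([
                e.a.id, e.a.kind.value, e.b.id, e.b.kind.value,
                e.etype.value, _format_weight(e.weight), e.provenance,
            ]) + "\n")


# ---------------------------------------------------------------------------
# merging and annotation
# ---------------------------------------------------------------------------

def merge(interactomes: Sequence[Interactome], build_tag: str = "") -> Interactome:
    """Node/edge union of validated interactomes; duplicate edges keep max weight."""
    out = Interactome(build_tag=build_tag or "+".join(n.build_tag for n in interactomes))
    for net in interactomes:
        for mol in net.nodes:
            out.add_node(mol)
        for e in net.edges:
            out.add_interaction(e)
        for node_id, ann in net.annotations.items():
            out.annotations.setdefault(node_id, ann)
    out.validate()
    return out


@dataclass
class AnnotationReport:
    n_rows: int = 0
    n_applied: int = 0
    n_ignored: int = 0


ANNOTATION_FIELDS = ("disease", "drug_target", "variability")


def annotate(net, path: Union[str, Path]) -> AnnotationReport:
    """Attach a node annotation table to an interactome or subnetwork.

    TSV columns ``node_id  field  value`` with field one of ``disease``,
    ``drug_target`` or ``variability``.  Rows whose id matches no node are
    counted and ignored.  Matching is by identifier (any kind).
    """
    known_ids = {mol.id for mol in net.nodes}
    report = AnnotationReport()
    path = Path(path)
    with open(path, "rt", encoding="utf-8") as fh:
        header = [c.strip() for c in fh.readline().rstrip("\n").split("\t")]
        if header[:3] != ["node_id", "field", "value"]:
            raise FormatError(f"{path}: bad header {header!r}, expected node_id/field/value")
        for row_no, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}: row {row_no}: expected 3 columns")
            node_id, fld, value = (p.strip() for p in parts[:3])
            if fld not in ANNOTATION_FIELDS:
                raise ValidationError(f"{path}: row {row_no}: unknown field {fld!r}")
            report.n_rows += 1
            if node_id not in known_ids:
                report.n_ignored += 1
                continue
            ann = net.annotations.setdefault(node_id, NodeAnnotation(node_id))
            if fld == "disease":
                ann.diseases.append(value)
            elif fld == "drug_target":
                ann.drug_targets.append(value)
            else:
                v = float(value)
                if not 0.0 <= v <= 100.0:
                    raise ValidationError(
                        f"{path}: row {row_no}: variability {v} outside [0, 100]"
                    )
                ann.variability = v
            report.n_applied += 1
    if report.n_ignored:
        logger.info("%s: %d annotation rows ignored (unknown ids)", path, report.n_ignored)
    return report
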