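"""Set algebra over subnetwork "layers" for cross-tissue / cross-run comparison.

A layer is a named set of edge keys with per-edge provenance; comparison is at
edge granularity because pathways are edge objects.  Flow values from distinct
runs are never merged — a union keeps each input's flow side by side under the
contributing layer's name.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

from .errors import ValidationError
from .flowcore import Subnetwork
from .interactome import EdgeType, Kind

__all__ = ["LayerOp", "Layer", "combine", "layer_from_subnetwork",
           "read_layer_json", "write_layer_json"]


class LayerOp(str, enum.Enum):
    UNION = "UNION"
    INTERSECTION = "INTERSECTION"
    DIFFERENCE = "DIFFERENCE"
    XOR = "XOR"


#: edge key: (a_id, a_kind, b_id, b_kind, etype), PPIs in canonical order
LayerEdgeKey = tuple[str, str, str, str, str]


def _canonical(a_id: str, a_kind: str, b_id: str, b_kind: str, etype: str) -> LayerEdgeKey:
    if etype == EdgeType.PPI.value and (b_id, b_kind) < (a_id, a_kind):
        a_id, a_kind, b_id, b_kind = b_id, b_kind, a_id, a_kind
    return (a_id, a_kind, b_id, b_kind, etype)


@dataclass
class Layer:
    """Named edge set; ``edges`` maps edge key -> per-source metadata
    (e.g. ``{"run A": {"flow": 0.3, "weight": 0.9}}``)."""

    name: str
    edges: dict[LayerEdgeKey, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("layer name must be non-empty")

    def __len__(self) -> int:
        return len(self.edges)

    @property
    def node_keys(self) -> set[tuple[str, str]]:
        out: set[tuple[str, str]] = set()
        for (a_id, a_kind, b_id, b_kind, _et) in self.edges:
            out.add((a_id, a_kind))
            out.add((b_id, b_kind))
        return out

    def project_nodes(self) -> set[tuple[str, str]]:
        """Node-granularity view (convenience projection)."""
        return self.node_keys


def layer_from_subnetwork(sub: Subnetwork, name: str = "") -> Layer:
    name = name or sub.name
    edges: dict[LayerEdgeKey, dict] = {}
    for inter, flow in sub.edges:
        key = _canonical(inter.a.id, inter.a.kind.value,
                         inter.b.id, inter.b.kind.value, inter.etype.value)
        edges[key] = {name: {"flow": flow, "weight": inter.weight}}
    return Layer(name=name, edges=edges)


def _merged_meta(key: LayerEdgeKey, *layers: Layer) -> dict:
    meta: dict = {}
    for lay in layers:
        if key in lay.edges:
            meta.update(lay.edges[key])
    return meta


def combine(x: Layer, y: Layer, op: Union[LayerOp, str], name: str = "") -> Layer:
    """Edge-set algebra.  DIFFERENCE is ``x \\ y`` (order matters)."""
    try:
        op = LayerOp(op.upper() if isinstance(op, str) else op)
    except ValueError:
        raise ValidationError(f"unknown layer operation {op!r}") from None
    kx, ky = set(x.edges), set(y.edges)
    if op is LayerOp.UNION:
        keys = kx | ky
    elif op is LayerOp.INTERSECTION:
        keys = kx & ky
    elif op is LayerOp.DIFFERENCE:
        keys = kx - ky
    else:
        keys = kx ^ ky
    return Layer(name=name or f"{op.value}({x.name},{y.name})",
                 edges={k: _merged_meta(k, x, y) for k in sorted(keys)})


# ---------------------------------------------------------------------------
# I/O — accepts either a layer JSON or a subnetwork JSON export
# ---------------------------------------------------------------------------

def write_layer_json(layer: Layer, path: Union[str, Path]) -> None:
    payload = {
        "name": layer.name,
        "edges": [{"key": list(k), "meta": m} for k, m in sorted(layer.edges.items())],
        "nodes": [list(n) for n in sorted(layer.node_keys)],
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def read_layer_json(path: Union[str, Path]) -> Layer:
    d = json.loads(Path(path).read_text())
    if "edges" in d and d["edges"] and isinstance(d["edges"][0], dict) and "a_id" in d["edges"][0]:
        # subnetwork export -> layer
        from .flowcore import subnetwork_from_dict
        return layer_from_subnetwork(subnetwork_from_dict(d))
    edges: dict[LayerEdgeKey, dict] = {}
    for row in d.get("edges", []):
        key = _canonical(*row["key"])
        edges[key] = dict(row.get("meta", {}))
    return Layer(name=d.get("name", "layer"), edges=edges)
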