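"""Declarative network topology with symbolic shape propagation.

Segmentation architectures are described here as plain data: a directed
acyclic graph of :class:`LayerNode` objects whose kinds (``conv_block``,
``pool``, ``dense_block``, ``transition_down``, ``transition_up``, ...)
carry enough information to derive every intermediate feature-map shape
and the trainable-parameter count *without* instantiating weights or
running a forward pass.  This makes the published per-layer "output size"
ledgers of both cascade stages a checkable contract: shape propagation is
pure arithmetic, so an architecture builder can be verified row by row.

Convolutions are assumed "same"-padded throughout, so spatial size changes
only at pooling / transition-down (halve) and upsampling / transition-up
(double) nodes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Iterator

__all__ = [
    "LayerNode",
    "LayerGraph",
    "ShapeEntry",
    "ShapeTable",
    "GraphError",
    "ShapeError",
    "propagate_shapes",
    "count_parameters",
]

#: node kinds understood by the shape engine and the model compiler
KINDS = (
    "input",
    "conv",
    "conv_block",
    "pool",
    "up",
    "dense_block",
    "transition_down",
    "transition_up",
    "concat",
    "conv1x1_out",
)


class GraphError(ValueError):
    """Structural problem in a layer graph (dangling input, cycle, ...)."""


class ShapeError(ValueError):
    """Shape propagation failed (odd size at a pooling node, ...)."""


@dataclass
class LayerNode:
    """One node of a network graph.

    ``params`` is kind-specific: ``conv_block``/``up``/``conv1x1_out`` take
    ``out_channels``; ``dense_block`` takes ``n_layers``, ``growth_rate``
    and ``mode`` (``concat_with_input`` or ``new_features_only``).
    """

    name: str
    kind: str
    params: dict = field(default_factory=dict)
    inputs: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise GraphError(f"unknown node kind {self.kind!r} for node {self.name!r}")
        if self.kind == "concat" and len(self.inputs) < 2:
            raise GraphError(f"concat node {self.name!r} needs >= 2 inputs")


class LayerGraph:
    """An ordered, acyclic collection of :class:`LayerNode` objects."""

    def __init__(self) -> None:
        self._nodes: dict[str, LayerNode] = {}

    # -- construction ---------------------------------------------------
    def add(self, name: str, kind: str, inputs: Iterable[str] = (), **params) -> LayerNode:
        if name in self._nodes:
            raise GraphError(f"duplicate node name {name!r}")
        inputs = list(inputs)
        for up in inputs:
            if up not in self._nodes:
                raise GraphError(f"node {name!r} references unknown input {up!r}")
        node = LayerNode(name=name, kind=kind, params=dict(params), inputs=inputs)
        self._nodes[name] = node
        return node

    # -- access ---------------------------------------------------------
    def __len__(self) -> int:
        return len(self._nodes)

    def __contains__(self, name: str) -> bool:
        return name in self._nodes

    def __getitem__(self, name: str) -> LayerNode:
        return self._nodes[name]

    def __iter__(self) -> Iterator[LayerNode]:
        # insertion order is a valid topological order by construction
        return iter(self._nodes.values())

    @property
    def names(self) -> list[str]:
        return list(self._nodes)

    def consumers(self, name: str) -> list[str]:
        return [n.name for n in self if name in n.inputs]

    # -- serialization --------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "nodes": [
                {"name": n.name, "kind": n.kind, "params": n.params, "inputs": n.inputs}
                for n in self
            ]
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LayerGraph":
        g = cls()
        for node_spec in d["nodes"]:
            g.add(node_spec["name"], node_spec["kind"], node_spec.get("inputs", ()),
                  **node_spec.get("params", {}))
        return g

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "LayerGraph":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class ShapeEntry:
    name: str
    size: tuple  # (H, W)
    channels: int


class ShapeTable:
    """Ordered (node, spatial size, channel count) records with name lookup."""

    def __init__(self, entries: list[ShapeEntry]) -> None:
        self.entries = entries
        self._by_name = {e.name: e for e in entries}

    def __iter__(self) -> Iterator[ShapeEntry]:
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, name: str) -> ShapeEntry:
        return self._by_name[name]

    def channels(self, name: str) -> int:
        return self._by_name[name].channels

    def size(self, name: str) -> tuple:
        return self._by_name[name].size

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        rows = [f"{e.name:30s} {e.size[0]}x{e.size[1]} x {e.channels}" for e in self]
        return "\n".join(rows)


def _halve(size: tuple, name: str) -> tuple:
    h, w = size
    if h % 2 or w % 2:
        raise ShapeError(f"node {name!r}: spatial size {size} not divisible by 2")
    return (h // 2, w // 2)


def propagate_shapes(graph: LayerGraph, input_size: tuple) -> ShapeTable:
    """Derive (spatial size, channels) for every node of ``graph``.

    ``input_size`` is ``(H, W, C)`` of the network input.  The result is
    independent of any weights; repeated calls yield identical tables.
    """
    h, w, c = input_size
    shapes: dict[str, ShapeEntry] = {}
    entries: list[ShapeEntry] = []

    for node in graph:
        if node.kind == "input":
            entry = ShapeEntry(node.name, (h, w), c)
        else:
            ins = []
            for up in node.inputs:
                if up not in shapes:
                    raise GraphError(f"node {node.name!r}: dangling input {up!r}")
                ins.append(shapes[up])
            if node.kind != "concat" and len(ins) != 1:
                raise GraphError(f"node {node.name!r} ({node.kind}) needs exactly one input")

            if node.kind in ("conv", "conv_block"):
                entry = ShapeEntry(node.name, ins[0].size, node.params["out_channels"])
            elif node.kind == "pool":
                entry = ShapeEntry(node.name, _halve(ins[0].size, node.name), ins[0].channels)
            elif node.kind == "up":
                sz = (ins[0].size[0] * 2, ins[0].size[1] * 2)
                entry = ShapeEntry(node.name, sz, node.params["out_channels"])
            elif node.kind == "dense_block":
                n, k = node.params["n_layers"], node.params["growth_rate"]
                mode = node.params.get("mode", "concat_with_input")
                if mode == "concat_with_input":
                    ch = ins[0].channels + n * k
                elif mode == "new_features_only":
                    if n == 0:
                        raise ShapeError(
                            f"dense block {node.name!r}: 0 layers in new_features_only "
                            "mode would produce an empty output"
                        )
                    ch = n * k
                else:
                    raise GraphError(f"dense block {node.name!r}: unknown mode {mode!r}")
                entry = ShapeEntry(node.name, ins[0].size, ch)
            elif node.kind == "transition_down":
                entry = ShapeEntry(node.name, _halve(ins[0].size, node.name), ins[0].channels)
            elif node.kind == "transition_up":
                src = graph[node.inputs[0]]
                if src.kind != "dense_block":
                    raise GraphError(
                        f"transition_up {node.name!r} must follow a dense block, "
                        f"got {src.kind!r}"
                    )
                ch = src.params["n_layers"] * src.params["growth_rate"]
                sz = (ins[0].size[0] * 2, ins[0].size[1] * 2)
                entry = ShapeEntry(node.name, sz, ch)
            elif node.kind == "concat":
                sz = ins[0].size
                for e in ins[1:]:
                    if e.size != sz:
                        raise ShapeError(
                            f"concat {node.name!r}: mismatched spatial sizes "
                            f"{[e.size for e in ins]}"
                        )
                entry = ShapeEntry(node.name, sz, sum(e.channels for e in ins))
            elif node.kind == "conv1x1_out":
                entry = ShapeEntry(node.name, ins[0].size, node.params.get("out_channels", 1))
            else:  # pragma: no cover - KINDS is closed
                raise GraphError(f"unhandled kind {node.kind!r}")
        shapes[node.name] = entry
        entries.append(entry)
    return ShapeTable(entries)


def count_parameters(graph: LayerGraph, input_size: tuple) -> int:
    """Trainable-parameter count implied by the graph.

    Counting rules mirror the model compiler exactly (3x3 biased convs in
    conv blocks and dense layers, 2x2 biased transposed convs at ``up``
    nodes, 3x3 at ``transition_up``, batch-norm gamma/beta in dense paths),
    so the symbolic count equals the instantiated model's count.
    """
    shapes = propagate_shapes(graph, input_size)
    total = 0
    for node in graph:
        cin = shapes[node.inputs[0]].channels if node.inputs else 0
        cout = shapes[node.name].channels
        if node.kind == "conv":
            total += (cin * 9 + 1) * cout
        elif node.kind == "conv_block":
            total += (cin * 9 + 1) * cout + (cout * 9 + 1) * cout
        elif node.kind == "up":
            total += cin * cout * 4 + cout
        elif node.kind == "dense_block":
            n, k = node.params["n_layers"], node.params["growth_rate"]
            m = cin
            for i in range(n):
                c = m + i * k
                total += 2 * c            # batch-norm gamma/beta
                total += (c * 9 + 1) * k  # 3x3 conv
        elif node.kind == "transition_down":
            total += 2 * cin + (cin + 1) * cin
        elif node.kind == "transition_up":
            total += cout * cout * 9 + cout
        elif node.kind == "conv1x1_out":
            total += (cin + 1) * cout
        # input / pool / concat carry no parameters
    return total
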