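"""Region decomposition of block-structured process graphs.

The fixture models (and any model this engine targets) are block-structured:
every gateway split has a matching join of the same kind, blocks nest
properly, and each container holds one start and one end event.  Under that
assumption the flow graph decomposes into a tree of regions — sequences,
AND blocks (parallel interleaving), XOR blocks (exclusive branches) and
sub-process bodies — which several consumers rely on:

* the token engine's Camunda-compatibility rule needs to know which pending
  XOR decisions guard optional tasks in *sibling* branches of an AND block;
* the brute-force trace oracle enumerates completion orders combinatorially
  over the region tree, independent of token semantics;
* the remaining-surgery-duration estimate sums durations per region
  (max over exclusive branches, sum over parallel ones).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ModelValidationError
from .model import FlowNode, NodeKind, ProcessModel

__all__ = [
    "TaskLeaf", "Block", "SubProcessRegion", "Sequence", "parse_model",
    "ModelStructure",
]


@dataclass
class TaskLeaf:
    node: FlowNode


@dataclass
class Sequence:
    items: list = field(default_factory=list)


@dataclass
class Block:
    kind: str  # "and" | "xor"
    split: str
    join: str
    branches: list[Sequence] = field(default_factory=list)

    @property
    def has_empty_branch(self) -> bool:
        return any(not b.items for b in self.branches)


@dataclass
class SubProcessRegion:
    node: FlowNode
    body: Sequence


def _single_outgoing(model: ProcessModel, node_id: str):
    out = model.outgoing(node_id)
    if len(out) != 1:
        raise ModelValidationError(
            f"node {node_id!r} is not block-structured (|outgoing|={len(out)})")
    return out[0]


def _matching_join(model: ProcessModel, split: FlowNode) -> str:
    """Walk one branch, counting nesting depth, until the matching join."""
    flow = model.outgoing(split.node_id)[0]
    depth = 0
    seen = set()
    while True:
        node = model.node(flow.target)
        if node.node_id in seen:
            raise ModelValidationError(f"cycle while matching gateway {split.node_id!r}")
        seen.add(node.node_id)
        gateway = node.kind in (NodeKind.XOR_GATEWAY, NodeKind.AND_GATEWAY)
        if gateway and len(model.incoming(node.node_id)) > 1:
            if depth == 0:
                return node.node_id
            depth -= 1
            flow = _single_outgoing(model, node.node_id)
        elif gateway:
            depth += 1
            flow = model.outgoing(node.node_id)[0]
        else:
            flow = _single_outgoing(model, node.node_id)


def _parse_from(model: ProcessModel, start_flow, stop_at: str) -> Sequence:
    """Parse the region sequence from a flow until reaching node *stop_at*."""
    seq = Sequence()
    flow = start_flow
    while True:
        node = model.node(flow.target)
        if node.node_id == stop_at:
            return seq
        if node.kind is NodeKind.USER_TASK or node.kind is NodeKind.CALL_ACTIVITY:
            seq.items.append(TaskLeaf(node))
            flow = _single_outgoing(model, node.node_id)
        elif node.kind is NodeKind.SUB_PROCESS:
            seq.items.append(SubProcessRegion(node, parse_container(model, node)))
            flow = _single_outgoing(model, node.node_id)
        elif node.kind in (NodeKind.XOR_GATEWAY, NodeKind.AND_GATEWAY):
            if len(model.outgoing(node.node_id)) <= 1:
                raise ModelValidationError(
                    f"unexpected join {node.node_id!r} before matching split")
            join = _matching_join(model, node)
            block = Block(
                kind="xor" if node.kind is NodeKind.XOR_GATEWAY else "and",
                split=node.node_id,
                join=join,
            )
            for out in model.outgoing(node.node_id):
                block.branches.append(_parse_from(model, out, stop_at=join))
            seq.items.append(block)
            flow = _single_outgoing(model, join)
        elif node.kind is NodeKind.END_EVENT:
            return seq
        elif node.kind is NodeKind.SIGNAL_BOUNDARY_EVENT:
            # boundary events sit off the sequence flow; never on the path
            raise ModelValidationError(
                f"boundary event {node.node_id!r} on the sequence path")
        else:
            raise ModelValidationError(
                f"unexpected node kind {node.kind.value!r} at {node.node_id!r}")


def parse_container(model: ProcessModel, container: FlowNode | None) -> Sequence:
    members = container.children if container is not None else model.nodes
    starts = [m for m in members if m.kind is NodeKind.START_EVENT]
    if len(starts) != 1:
        raise ModelValidationError("container needs exactly one start event")
    first = _single_outgoing(model, starts[0].node_id)
    return _parse_from(model, first, stop_at="\x00never")


class ModelStructure:
    """Precomputed region facts for one :class:`ProcessModel`."""

    def __init__(self, model: ProcessModel):
        self.model = model
        self.root = parse_container(model, None)
        #: split id -> Block
        self.blocks: dict[str, Block] = {}
        #: task id -> list of (block, branch index) from outermost to innermost
        self.enclosing: dict[str, list[tuple[Block, int]]] = {}
        self._index(self.root, [])

    def _index(self, seq: Sequence, stack: list[tuple[Block, int]]) -> None:
        for item in seq.items:
            if isinstance(item, TaskLeaf):
                self.enclosing[item.node.node_id] = list(stack)
            elif isinstance(item, SubProcessRegion):
                self._index(item.body, stack)
            elif isinstance(item, Block):
                self.blocks[item.split] = item
                for idx, branch in enumerate(item.branches):
                    self._index(branch, stack + [(item, idx)])

    # -- queries -----------------------------------------------------------

    def branch_tasks(self, block: Block, branch_idx: int) -> list[str]:
        out: list[str] = []
        _collect_tasks(block.branches[branch_idx], out)
        return out

    def optional_guard(self, block: Block) -> str | None:
        """If *block* is an XOR bypass around a single optional task, its id."""
        if block.kind != "xor" or len(block.branches) != 2:
            return None
        tasks = [self.branch_tasks(block, i) for i in range(2)]
        empties = [i for i, t in enumerate(tasks) if not t]
        if len(empties) != 1:
            return None
        guarded = tasks[1 - empties[0]]
        if len(guarded) == 1:
            return guarded[0]
        return None

    def bypass_branch(self, block: Block) -> int | None:
        for i, b in enumerate(block.branches):
            if not b.items:
                return i
        return None

    def mark_optional_steps(self) -> None:
        """Flag tasks guarded by an XOR bypass as optional on the model."""
        for block in self.blocks.values():
            guarded = self.optional_guard(block)
            if guarded is not None:
                self.model.node(guarded).optional_step = True


def _collect_tasks(seq: Sequence, out: list[str]) -> None:
    for item in seq.items:
        if isinstance(item, TaskLeaf):
            out.append(item.node.node_id)
        elif isinstance(item, SubProcessRegion):
            _collect_tasks(item.body, out)
        elif isinstance(item, Block):
            for b in item.branches:
                _collect_tasks(b, out)
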