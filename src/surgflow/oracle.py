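"""Brute-force enumeration of accepted complete traces.

Small process fragments admit exhaustive enumeration of every legal
completion order, which serves as the independent oracle for both engines
and for path-count claims (a block of five steps in variable order with one
of them optional already admits 4! + 5! = 144 complete traces).

The enumeration here is *combinatorial*: it works on the structural region
tree (BPMN) or the sentry graph (CMMN), never on the token/lifecycle
engines themselves.  The dual, engine-driven trace sets used for
equivalence checking are provided separately and clearly labeled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb, factorial

from .cmmn import replay_case, start_case
from .errors import SurgflowError
from .model import CaseModel, ItemKind, PlanItem, ProcessModel
from .structure import Block, ModelStructure, Sequence, SubProcessRegion, TaskLeaf

__all__ = [
    "TraceSet",
    "enumerate_traces",
    "count_traces",
    "closed_form_variable_block",
    "engine_accepted_traces",
]

DEFAULT_LIMIT = 10_000


@dataclass
class TraceSet:
    traces: set[tuple[str, ...]] = field(default_factory=set)
    truncated: bool = False

    def __len__(self):
        return len(self.traces)

    def __contains__(self, trace):
        return tuple(trace) in self.traces


class _Limit:
    def __init__(self, n: int):
        self.n = n
        self.hit = False

    def room(self, have: int) -> bool:
        if have >= self.n:
            self.hit = True
            return False
        return True


# ---------------------------------------------------------------------------
# combinatorial enumeration
# ---------------------------------------------------------------------------


def enumerate_traces(model: ProcessModel | CaseModel,
                     limit: int = DEFAULT_LIMIT) -> TraceSet:
    """All complete traces the notation's semantics accept, up to *limit*.

    BPMN: every interleaving of parallel branches, one branch per exclusive
    block (the bypass counts, so optional steps may be skipped).  CMMN:
    stage by stage, every sentry-respecting order over the required items
    plus any subset of optional items — optionals may run at any later point
    until their stage closes, and (with exclusive paths modeled as optional
    siblings) several or no "exclusive" branches may run.
    """
    lim = _Limit(limit)
    if isinstance(model, ProcessModel):
        structure = ModelStructure(model)
        structure.mark_optional_steps()
        traces = set(_region_traces(structure.root, lim))
    else:
        traces = _case_traces(model, lim)
    return TraceSet(traces=traces, truncated=lim.hit)


def _region_traces(region, lim: _Limit) -> set[tuple[str, ...]]:
    if isinstance(region, TaskLeaf):
        if region.node.kind.value == "user_task":
            return {(region.node.node_id,)}
        return {()}  # call activities are containers, not steps
    if isinstance(region, SubProcessRegion):
        return _region_traces(region.body, lim)
    if isinstance(region, Sequence):
        acc: set[tuple[str, ...]] = {()}
        for item in region.items:
            part = _region_traces(item, lim)
            nxt = set()
            for a in acc:
                for b in part:
                    if not lim.room(len(nxt)):
                        return nxt
                    nxt.add(a + b)
            acc = nxt
        return acc
    if isinstance(region, Block):
        branch_sets = [_region_traces(b, lim) for b in region.branches]
        if region.kind == "xor":
            out: set[tuple[str, ...]] = set()
            for s in branch_sets:
                out |= s
            return out
        out = set()
        for combo in _product(branch_sets):
            for inter in _interleave(list(combo)):
                if not lim.room(len(out)):
                    return out
                out.add(inter)
        return out
    raise TypeError(f"unexpected region {region!r}")


def _product(sets):
    if not sets:
        yield ()
        return
    for head in sets[0]:
        for rest in _product(sets[1:]):
            yield (head,) + rest


def _interleave(seqs: list[tuple[str, ...]]):
    seqs = [s for s in seqs if s]
    if not seqs:
        yield ()
        return
    for i, s in enumerate(seqs):
        rest = seqs[:i] + [s[1:]] + seqs[i + 1:]
        for tail in _interleave(rest):
            yield (s[0],) + tail


def _case_groups(case: CaseModel) -> list[PlanItem]:
    top = [i for i in case.plan_items if i.kind is not ItemKind.EVENT_LISTENER]
    if top and all(i.kind is ItemKind.STAGE for i in top):
        return top
    pseudo = PlanItem(item_id=f"{case.case_id}__root", kind=ItemKind.STAGE,
                      children=top)
    return [pseudo]


def _case_traces(case: CaseModel, lim: _Limit) -> set[tuple[str, ...]]:
    groups = _case_groups(case)
    out: set[tuple[str, ...]] = set()

    def rec(idx: int, completed: frozenset, prefix: tuple):
        if lim.hit:
            return
        if idx == len(groups):
            if lim.room(len(out)):
                out.add(prefix)
            return
        stage = groups[idx]
        for order in _stage_orders(stage, completed, lim):
            rec(idx + 1,
                completed | frozenset(order) | {stage.item_id},
                prefix + order)

    rec(0, frozenset(), ())
    return out


def _stage_orders(stage: PlanItem, completed0: frozenset, lim: _Limit):
    tasks = [c for c in stage.children if c.kind is ItemKind.HUMAN_TASK]
    required = {t.item_id for t in tasks if t.required}
    orders: list[tuple[str, ...]] = []

    def satisfied(item: PlanItem, completed) -> bool:
        if not item.entry_criteria:
            return True
        return any(all(src in completed for src, _ in s.on_parts)
                   for s in item.entry_criteria)

    def dfs(completed: frozenset, order: tuple):
        if lim.hit:
            return
        done = set(order)
        if required <= done:
            # the stage may close here; un-run optionals become disabled
            if lim.room(len(orders)):
                orders.append(order)
        for t in tasks:
            if t.item_id in done:
                continue
            if satisfied(t, completed):
                dfs(completed | {t.item_id}, order + (t.item_id,))

    dfs(completed0, ())
    return orders


# ---------------------------------------------------------------------------
# counting
# ---------------------------------------------------------------------------


def count_traces(model: ProcessModel | CaseModel,
                 limit: int = DEFAULT_LIMIT) -> int:
    """Number of accepted complete traces.

    For BPMN this is computed exactly from the region tree without
    materializing traces (interleavings enter through multinomial
    coefficients); case models fall back to enumeration.
    """
    if isinstance(model, ProcessModel):
        structure = ModelStructure(model)
        structure.mark_optional_steps()
        return sum(_region_counts(structure.root).values())
    ts = enumerate_traces(model, limit=limit)
    if ts.truncated:
        raise SurgflowError(f"trace count exceeds the {limit} enumeration limit")
    return len(ts)


def _region_counts(region) -> dict[int, int]:
    """Map trace length -> number of distinct traces of that length."""
    if isinstance(region, TaskLeaf):
        return {1: 1} if region.node.kind.value == "user_task" else {0: 1}
    if isinstance(region, SubProcessRegion):
        return _region_counts(region.body)
    if isinstance(region, Sequence):
        acc = {0: 1}
        for item in region.items:
            part = _region_counts(item)
            nxt: dict[int, int] = {}
            for la, ca in acc.items():
                for lb, cb in part.items():
                    nxt[la + lb] = nxt.get(la + lb, 0) + ca * cb
            acc = nxt
        return acc
    if isinstance(region, Block):
        branch_counts = [_region_counts(b) for b in region.branches]
        if region.kind == "xor":
            merged: dict[int, int] = {}
            for bc in branch_counts:
                for l, c in bc.items():
                    merged[l] = merged.get(l, 0) + c
            return merged
        acc = {0: 1}
        for bc in branch_counts:
            nxt = {}
            for la, ca in acc.items():
                for lb, cb in bc.items():
                    n = la + lb
                    nxt[n] = nxt.get(n, 0) + ca * cb * comb(n, lb)
            acc = nxt
        return acc
    raise TypeError(f"unexpected region {region!r}")


def closed_form_variable_block(k: int, m: int) -> int:
    """Complete traces of a variable-order block: *k* required and *m*
    optional steps, any order, optionals skippable:
    ``sum_j C(m, j) * (k + j)!``."""
    return sum(comb(m, j) * factorial(k + j) for j in range(m + 1))


# ---------------------------------------------------------------------------
# engine-driven trace sets (the dual route for equivalence checks)
# ---------------------------------------------------------------------------


def engine_accepted_traces(model: ProcessModel | CaseModel,
                           camunda_compat: bool = False,
                           limit: int = DEFAULT_LIMIT) -> TraceSet:
    """Complete traces accepted by the *engine* (depth-first over choices).

    This is deliberately the other route: it executes the token / lifecycle
    engine rather than the combinatorial enumeration, so the two can be
    compared on small fragments.
    """
    lim = _Limit(limit)
    out: set[tuple[str, ...]] = set()
    if isinstance(model, ProcessModel):
        from .bpmn import start_process

        def rec(inst):
            if lim.hit:
                return
            probe = inst.copy()
            probe.skip_pending_optionals()
            if probe.is_complete():
                if lim.room(len(out)):
                    out.add(inst.trace.as_tuple())
            for t in sorted(inst.activatable_tasks()):
                clone = inst.copy()
                try:
                    clone.complete_task(t)
                except SurgflowError:
                    continue
                rec(clone)

        rec(start_process(model, camunda_compat=camunda_compat))
    else:
        all_tasks = [t.item_id for t in model.human_tasks()]

        def closable(inst) -> bool:
            probe = inst.copy()
            try:
                from .cmmn import _force_startable  # stage completion helper
                while True:
                    try:
                        probe.complete_case()
                        probe.close_case()
                        return True
                    except SurgflowError:
                        stages = [s for s in probe.case.stages()
                                  if probe.item_states[s.item_id] == "active"]
                        progressed = False
                        for s in stages:
                            try:
                                probe.complete_stage(s.item_id)
                                progressed = True
                            except SurgflowError:
                                continue
                        if not progressed:
                            return False
            except SurgflowError:
                return False

        def rec(inst, order):
            if lim.hit:
                return
            if closable(inst):
                if lim.room(len(out)):
                    out.add(tuple(order))
            for t in all_tasks:
                if inst.item_states[t] == "completed":
                    continue
                clone = inst.copy()
                try:
                    replayed = replay_case(model, list(order) + [t])
                except SurgflowError:
                    continue
                rec(replayed, order + [t])

        rec(start_case(model), [])
    return TraceSet(traces=out, truncated=lim.hit)
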