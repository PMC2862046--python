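"""Host-independent dataflow engine: typed workers, graphs, loop semantics.

A *worker* is a processing node with named, semantically-typed input and
output ports.  Workers are wired into an acyclic :class:`WorkflowGraph`;
edges carry payloads between ports and are type-checked before anything
runs.  The engine also provides the two loop constructs used to stream
paged data through a workflow body:

* a native FOR-style loop (:func:`run_paged_loop`) that draws pages from a
  registered source while items remain, and
* the historical *fail/retry emulation* (:func:`run_until_exhausted`): the
  loop body ends in a has-next → fail-if-true chain, the fail raises a
  loop-continue signal, and the engine's retry mechanism re-runs the nested
  workflow until the source is exhausted.

Both traversals are equivalent — each item is processed exactly once and the
body runs ceiling(n/p) times — and the test suite holds them to that.
State shared between workers (e.g. page cursors) lives in an explicit
string-keyed registry scoped to a single run, never in globals.
"""

from __future__ import annotations

import graphlib
import math
from collections.abc import Callable
from dataclasses import dataclass, field
from typing import Any

__all__ = [
    "SEMANTIC_TYPES",
    "register_semantic_type",
    "WorkerSpec",
    "Worker",
    "Edge",
    "RetryPolicy",
    "WorkflowGraph",
    "RunContext",
    "ExecutionTrace",
    "WiringError",
    "ExecutionError",
    "LoopContinue",
    "fail_if_true",
    "run_workflow",
    "run_paged_loop",
    "run_until_exhausted",
    "ListSource",
]

# Registered semantic-type vocabulary for ports; extensible at import time
# (e.g. the clustering workers register "clustering-result").
SEMANTIC_TYPES: set[str] = {"molecule-list", "string", "number", "table", "path"}


def register_semantic_type(name: str) -> None:
    SEMANTIC_TYPES.add(name)


class WiringError(ValueError):
    """A workflow failed validation before execution (bad edge, port, type)."""


class ExecutionError(RuntimeError):
    """A node failed with retries exhausted; carries the node id."""

    def __init__(self, node_id: str, message: str):
        super().__init__(f"node {node_id!r}: {message}")
        self.node_id = node_id


class LoopContinue(Exception):
    """Signal raised by fail-if-true to request a re-run of the loop body."""


@dataclass(frozen=True)
class WorkerSpec:
    """Port declaration of a worker: (port name, semantic type) pairs."""

    name: str
    input_ports: tuple[tuple[str, str], ...] = ()
    output_ports: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        for ports in (self.input_ports, self.output_ports):
            names = [p for p, _ in ports]
            if len(set(names)) != len(names):
                raise WiringError(f"worker {self.name}: duplicate port names")
            for pname, ptype in ports:
                if ptype not in SEMANTIC_TYPES:
                    raise WiringError(
                        f"worker {self.name}: port {pname!r} has unregistered "
                        f"semantic type {ptype!r}"
                    )

    def input_type(self, port: str) -> str:
        for p, t in self.input_ports:
            if p == port:
                return t
        raise WiringError(f"worker {self.name} has no input port {port!r}")

    def output_type(self, port: str) -> str:
        for p, t in self.output_ports:
            if p == port:
                return t
        raise WiringError(f"worker {self.name} has no output port {port!r}")


@dataclass
class Worker:
    """A spec plus the function executing it: inputs dict → outputs dict."""

    spec: WorkerSpec
    fn: Callable[[dict[str, Any], "RunContext"], dict[str, Any]]

    def execute(self, inputs: dict[str, Any], context: "RunContext") -> dict[str, Any]:
        return self.fn(inputs, context)


@dataclass(frozen=True)
class Edge:
    source_node: str
    source_port: str
    target_node: str
    target_port: str

    @classmethod
    def parse(cls, text: str) -> "Edge":
        """Parse the config notation ``"node.port -> node.port"``."""
        try:
            left, right = (s.strip() for s in text.split("->"))
            sn, sp = left.rsplit(".", 1)
            tn, tp = right.rsplit(".", 1)
        except ValueError as exc:
            raise WiringError(f"malformed edge {text!r}") from exc
        return cls(sn, sp, tn, tp)


@dataclass
class RetryPolicy:
    """Retry budget for one node (typically a nested subworkflow)."""

    max_retries: int = 0
    applies_to: str | None = None

    def __post_init__(self) -> None:
        if self.max_retries < 0:
            raise WiringError("max_retries must be >= 0")


@dataclass
class RunContext:
    """Run-scoped state: the string-keyed object registry."""

    registry: dict[str, Any] = field(default_factory=dict)


@dataclass
class ExecutionTrace:
    """What happened during a run: per-node status, retries, payload log."""

    node_status: dict[str, str] = field(default_factory=dict)  # pending/succeeded/failed/retried
    retry_counts: dict[str, int] = field(default_factory=dict)
    payload_log: list[tuple[str, str, str]] = field(default_factory=list)
    body_runs: int = 0
    pages: list[list[Any]] = field(default_factory=list)

    def log_payload(self, node: str, port: str, payload: Any) -> None:
        summary = type(payload).__name__
        try:
            summary += f"[{len(payload)}]"
        except TypeError:
            summary = repr(payload)[:80]
        self.payload_log.append((node, port, summary))


class WorkflowGraph:
    """Workers keyed by node id, wired by typed edges; acyclic at the top level.

    A nested subworkflow appears as a single node (see
    :meth:`chemflow.workers.subworkflow_worker`).
    """

    def __init__(
        self,
        nodes: dict[str, Worker],
        edges: list[Edge | str],
        retry_policy: RetryPolicy | None = None,
    ):
        self.nodes = dict(nodes)
        self.edges = [Edge.parse(e) if isinstance(e, str) else e for e in edges]
        self.retry_policy = retry_policy or RetryPolicy()
        self.validate()

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        for e in self.edges:
            for nid in (e.source_node, e.target_node):
                if nid not in self.nodes:
                    raise WiringError(f"edge references unknown node {nid!r}")
            src_t = self.nodes[e.source_node].spec.output_type(e.source_port)
            dst_t = self.nodes[e.target_node].spec.input_type(e.target_port)
            if src_t != dst_t:
                raise WiringError(
                    f"type mismatch on edge {e.source_node}.{e.source_port} "
                    f"({src_t}) -> {e.target_node}.{e.target_port} ({dst_t})"
                )
        targets: set[tuple[str, str]] = set()
        for e in self.edges:
            key = (e.target_node, e.target_port)
            if key in targets:
                raise WiringError(f"input port {key[0]}.{key[1]} is wired twice")
            targets.add(key)
        self._toposort()  # raises on cycles

    def _toposort(self) -> list[str]:
        ts: graphlib.TopologicalSorter = graphlib.TopologicalSorter()
        for nid in self.nodes:
            ts.add(nid)
        for e in self.edges:
            ts.add(e.target_node, e.source_node)
        try:
            return list(ts.static_order())
        except graphlib.CycleError as exc:
            raise WiringError(f"workflow graph contains a cycle: {exc.args[1]}") from exc

    # -- introspection -----------------------------------------------------

    def unbound_inputs(self) -> list[tuple[str, str, str]]:
        wired = {(e.target_node, e.target_port) for e in self.edges}
        out = []
        for nid, worker in self.nodes.items():
            for pname, ptype in worker.spec.input_ports:
                if (nid, pname) not in wired:
                    out.append((nid, pname, ptype))
        return out

    def terminal_outputs(self) -> list[tuple[str, str, str]]:
        wired = {(e.source_node, e.source_port) for e in self.edges}
        out = []
        for nid, worker in self.nodes.items():
            for pname, ptype in worker.spec.output_ports:
                if (nid, pname) not in wired:
                    out.append((nid, pname, ptype))
        return out


def fail_if_true(flag: str) -> str:
    """Raise a loop-continue signal when the text value is true.

    The comparison is case-insensitive and whitespace-trimmed; only the
    texts "true" and "false" are legal input.
    """
    if not isinstance(flag, str):
        raise ValueError(f"fail_if_true expects a text flag, got {type(flag).__name__}")
    norm = flag.strip().lower()
    if norm == "true":
        raise LoopContinue("flag was true")
    if norm == "false":
        return flag
    raise ValueError(f"fail_if_true expects 'true' or 'false', got {flag!r}")


def run_workflow(
    graph: WorkflowGraph,
    inputs: dict[str, Any] | None = None,
    context: RunContext | None = None,
    trace: ExecutionTrace | None = None,
) -> dict[str, Any]:
    """Execute a validated workflow; returns all terminal output payloads.

    ``inputs`` binds top-level input ports by ``"node.port"`` key.  Each node
    runs at most ``1 + max_retries`` times (retries only for the node the
    retry policy names).  A :class:`LoopContinue` raised by a node without a
    retry budget propagates to the caller — that is how a nested loop body
    signals its enclosing retry mechanism.
    """
    inputs = dict(inputs or {})
    context = context or RunContext()
    trace = trace or ExecutionTrace()
    graph.validate()

    required = {f"{nid}.{port}" for nid, port, _ in graph.unbound_inputs()}
    missing = required - set(inputs)
    if missing:
        raise WiringError(f"unbound top-level inputs: {sorted(missing)}")
    unknown = set(inputs) - required
    if unknown:
        raise WiringError(f"input bindings do not match any unbound port: {sorted(unknown)}")

    payloads: dict[tuple[str, str], Any] = {}
    for key, value in inputs.items():
        nid, port = key.rsplit(".", 1)
        payloads[(nid, port)] = value

    in_edges: dict[str, list[Edge]] = {nid: [] for nid in graph.nodes}
    for e in graph.edges:
        in_edges[e.target_node].append(e)

    for nid in graph._toposort():
        worker = graph.nodes[nid]
        node_inputs = {}
        for pname, _ in worker.spec.input_ports:
            if (nid, pname) in payloads:
                node_inputs[pname] = payloads[(nid, pname)]
        for e in in_edges[nid]:
            node_inputs[e.target_port] = payloads[(e.source_node, e.source_port)]
        trace.node_status[nid] = "pending"
        budget = (
            graph.retry_policy.max_retries
            if graph.retry_policy.applies_to == nid
            else 0
        )
        attempt = 0
        while True:
            try:
                outputs = worker.execute(node_inputs, context)
                break
            except LoopContinue:
                if attempt < budget:
                    attempt += 1
                    trace.node_status[nid] = "retried"
                    trace.retry_counts[nid] = attempt
                    continue
                raise
            except Exception as exc:
                if attempt < budget:
                    attempt += 1
                    trace.node_status[nid] = "retried"
                    trace.retry_counts[nid] = attempt
                    continue
                trace.node_status[nid] = "failed"
                raise ExecutionError(nid, str(exc)) from exc
        trace.node_status[nid] = "succeeded"
        for pname, _ in worker.spec.output_ports:
            if pname not in outputs:
                trace.node_status[nid] = "failed"
                raise ExecutionError(nid, f"worker produced no payload for port {pname!r}")
            payloads[(nid, pname)] = outputs[pname]
            trace.log_payload(nid, pname, outputs[pname])

    return {
        f"{nid}.{port}": payloads[(nid, port)]
        for nid, port, _ in graph.terminal_outputs()
        if (nid, port) in payloads
    }


# ---------------------------------------------------------------------------
# Paged sources and loop constructs


class ListSource:
    """In-memory paged source over a list; the minimal LIMIT/OFFSET emulator."""

    def __init__(self, items: list[Any], page_size: int):
        if page_size <= 0:
            raise ValueError("page size must be positive")
        self.items = list(items)
        self.page_size = page_size
        self.offset = 0

    def has_remaining(self) -> bool:
        return self.offset < len(self.items)

    def next_page(self) -> list[Any]:
        page = self.items[self.offset : self.offset + self.page_size]
        self.offset += self.page_size
        return page

    def has_next(self) -> str:
        return "true" if self.has_remaining() else "false"

    def reset(self) -> None:
        self.offset = 0


def run_paged_loop(
    source, body: Callable[[Any], Any], trace: ExecutionTrace | None = None
) -> ExecutionTrace:
    """Native FOR-style loop: run ``body`` once per page until exhausted.

    ``has_remaining`` is evaluated before the first body run, so an empty
    source executes the body zero times.
    """
    trace = trace or ExecutionTrace()
    while source.has_remaining():
        page = source.next_page()
        body(page)
        trace.body_runs += 1
        trace.pages.append(list(page))
    return trace


def run_until_exhausted(
    subworkflow: WorkflowGraph,
    state_id: str,
    context: RunContext,
    max_retries: int | None = None,
    inputs: dict[str, Any] | None = None,
) -> ExecutionTrace:
    """Fail/retry loop emulation: re-run a nested workflow until exhausted.

    The subworkflow must contain a has-next → fail-if-true chain bound to a
    paged source registered in the context under ``state_id``; each run
    consumes one page, and the loop-continue signal raised while pages
    remain triggers a re-run.  Raises :class:`ExecutionError` when the retry
    budget is smaller than the number of pages still unread.
    """
    if state_id not in context.registry:
        raise WiringError(f"no paged source registered under {state_id!r}")
    source = context.registry[state_id]
    if max_retries is None:
        max_retries = subworkflow.retry_policy.max_retries
    trace = ExecutionTrace()
    if not source.has_remaining():  # empty source: zero body executions
        return trace
    retries = 0
    while True:
        before = source.offset
        try:
            run_workflow(subworkflow, inputs=inputs, context=context, trace=trace)
            trace.body_runs += 1
            trace.pages.append(list(context.registry.get(f"{state_id}:last_page", [])))
            return trace
        except LoopContinue:
            if source.offset == before:  # body drew no page: the loop is stuck
                raise ExecutionError(
                    state_id, "loop body did not advance the paged source"
                ) from None
            trace.body_runs += 1
            trace.pages.append(list(context.registry.get(f"{state_id}:last_page", [])))
            retries += 1
            if retries > max_retries:
                remaining = len(source.items) - source.offset if hasattr(source, "items") else None
                pages_left = (
                    math.ceil(remaining / source.page_size)
                    if remaining is not None
                    else "unknown"
                )
                raise ExecutionError(
                    state_id,
                    f"retry budget {max_retries} exhausted with {pages_left} pages remaining",
                ) from None
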