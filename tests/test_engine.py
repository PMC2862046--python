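"""Dataflow engine: typed wiring, retries, and loop-construct semantics."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import chemflow as cf
from chemflow.engine import ListSource
from chemflow.workers import make_worker


def paging_body(state_id="src"):
    return cf.WorkflowGraph(
        nodes={
            "page": make_worker("get-page", {"state_id": state_id}),
            "next": make_worker("has-next", {"state_id": state_id}),
            "fail": make_worker("fail-if-true"),
        },
        edges=["page.page -> next.trigger", "next.has_next -> fail.flag"],
    )


def emulate(n, page_size, max_retries=10_000):
    ctx = cf.RunContext()
    ctx.registry["src"] = ListSource(list(range(n)), page_size)
    return cf.run_until_exhausted(paging_body(), "src", ctx, max_retries=max_retries)


def native(n, page_size):
    return cf.run_paged_loop(ListSource(list(range(n)), page_size), lambda page: None)


class TestFailIfTrue:
    def test_true_raises_loop_continue(self):
        with pytest.raises(cf.LoopContinue):
            cf.fail_if_true("true")

    def test_false_passes_through(self):
        assert cf.fail_if_true("false") == "false"

    @pytest.mark.parametrize("flag", ["TRUE", " True\n", "tRuE"])
    def test_case_insensitive_whitespace_trimmed(self, flag):
        with pytest.raises(cf.LoopContinue):
            cf.fail_if_true(flag)

    @pytest.mark.parametrize("flag", ["yes", "", "1", "false-ish"])
    def test_other_text_is_a_value_error(self, flag):
        with pytest.raises(ValueError):
            cf.fail_if_true(flag)


class TestRunWorkflow:
    def test_identity_passthrough(self):
        g = cf.WorkflowGraph(nodes={"id": make_worker("identity")}, edges=[])
        assert cf.run_workflow(g, {"id.value": "x"}) == {"id.value": "x"}

    def test_two_node_chain_counts_heavy_atoms(self):
        g = cf.WorkflowGraph(
            nodes={"parse": make_worker("parse-smiles"), "count": make_worker("count-atoms")},
            edges=["parse.molecules -> count.molecules"],
        )
        out = cf.run_workflow(g, {"parse.smiles": "CCO"})
        assert out["count.count"] == 3

    def test_type_mismatched_edge_rejected_before_running(self):
        with pytest.raises(cf.WiringError, match="type mismatch"):
            cf.WorkflowGraph(
                nodes={"parse": make_worker("parse-smiles"), "id": make_worker("identity")},
                edges=["parse.molecules -> id.value"],
            )

    def test_cycle_rejected(self):
        with pytest.raises(cf.WiringError, match="cycle"):
            cf.WorkflowGraph(
                nodes={"a": make_worker("identity"), "b": make_worker("identity")},
                edges=["a.value -> b.value", "b.value -> a.value"],
            )

    def test_missing_input_binding_rejected(self):
        g = cf.WorkflowGraph(nodes={"id": make_worker("identity")}, edges=[])
        with pytest.raises(cf.WiringError, match="unbound"):
            cf.run_workflow(g, {})

    def test_failed_node_reports_its_id(self):
        g = cf.WorkflowGraph(nodes={"fail": make_worker("fail-if-true")}, edges=[])
        with pytest.raises(cf.ExecutionError, match="fail"):
            cf.run_workflow(g, {"fail.flag": "neither"})

    def test_deterministic_outputs(self):
        g = cf.WorkflowGraph(
            nodes={"parse": make_worker("parse-smiles"), "smi": make_worker("write-smiles")},
            edges=["parse.molecules -> smi.molecules"],
        )
        runs = [cf.run_workflow(g, {"parse.smiles": "OCC c1ccccc1"}) for _ in range(2)]
        assert runs[0]["smi.smiles"] == runs[1]["smi.smiles"]


class TestRetryBound:
    def test_node_runs_at_most_one_plus_max_retries(self):
        calls = []

        def flaky(inputs, ctx):
            calls.append(1)
            if len(calls) < 3:
                raise RuntimeError("transient")
            return {"value": inputs["value"]}

        spec = cf.WorkerSpec("flaky", (("value", "string"),), (("value", "string"),))
        g = cf.WorkflowGraph(
            nodes={"n": cf.Worker(spec, flaky)},
            edges=[],
            retry_policy=cf.RetryPolicy(max_retries=1, applies_to="n"),
        )
        with pytest.raises(cf.ExecutionError):
            cf.run_workflow(g, {"n.value": "x"})
        assert len(calls) == 2  # 1 + max_retries

        calls.clear()
        g2 = cf.WorkflowGraph(
            nodes={"n": cf.Worker(spec, flaky)},
            edges=[],
            retry_policy=cf.RetryPolicy(max_retries=2, applies_to="n"),
        )
        trace = cf.ExecutionTrace()
        out = cf.run_workflow(g2, {"n.value": "x"}, trace=trace)
        assert out == {"n.value": "x"}
        assert trace.retry_counts["n"] == 2
        assert trace.node_status["n"] == "succeeded"


class TestLoopSemantics:
    @pytest.mark.parametrize(
        "n,page_size,expected",
        [(0, 3, 0), (7, 7, 1), (10, 3, 4), (100, 7, 15), (1, 5, 1)],
    )
    def test_body_runs_is_page_count(self, n, page_size, expected):
        assert native(n, page_size).body_runs == expected
        assert emulate(n, page_size).body_runs == expected

    def test_exactly_once_and_identical_traversals(self):
        for n, p in [(10, 3), (25, 4), (9, 9), (5, 10)]:
            t_native = native(n, p)
            t_emul = emulate(n, p)
            flat = [x for page in t_native.pages for x in page]
            assert flat == list(range(n))  # exactly once, in order
            assert t_native.pages == t_emul.pages

    def test_empty_store_runs_body_zero_times(self):
        assert native(0, 4).pages == []
        assert emulate(0, 4).pages == []

    def test_retry_budget_smaller_than_page_count_errors(self):
        with pytest.raises(cf.ExecutionError, match="pages remaining"):
            emulate(10, 3, max_retries=1)

    def test_unregistered_state_id_rejected(self):
        with pytest.raises(cf.WiringError):
            cf.run_until_exhausted(paging_body(), "nope", cf.RunContext())

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(n=st.integers(0, 60), p=st.integers(1, 12))
    def test_paging_property_ceiling_and_exactly_once(self, n, p):
        trace = emulate(n, p)
        assert trace.body_runs == math.ceil(n / p)
        assert [x for page in trace.pages for x in page] == list(range(n))
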