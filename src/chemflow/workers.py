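"""Built-in worker registry: library operations exposed as typed workers.

Every worker wraps one library operation behind the engine's port contract.
The registry is grouped by function (file I/O, SMILES tools, InChI, database
I/O, molecular descriptors, clustering, miscellaneous) for discoverability
from the CLI's ``workers-list`` command.  Workers are created from a name
plus a params mapping, which is how declarative YAML workflow configs refer
to them.
"""

from __future__ import annotations

from collections.abc import Callable
from dataclasses import dataclass
from typing import Any

from . import art2a, chem_io, enumeration, qsar, store, structure
from .engine import (
    RunContext,
    Worker,
    WorkerSpec,
    WorkflowGraph,
    fail_if_true,
    register_semantic_type,
)

__all__ = ["WORKER_REGISTRY", "make_worker", "worker_catalogue", "subworkflow_worker"]

register_semantic_type("clustering-result")
register_semantic_type("reaction")


@dataclass(frozen=True)
class WorkerFactory:
    category: str
    spec: WorkerSpec
    build: Callable[[dict[str, Any]], Callable[[dict, RunContext], dict]]


WORKER_REGISTRY: dict[str, WorkerFactory] = {}


def _register(category: str, name: str, inputs, outputs):
    spec = WorkerSpec(name, tuple(inputs), tuple(outputs))

    def deco(builder):
        WORKER_REGISTRY[name] = WorkerFactory(category, spec, builder)
        return builder

    return deco


def make_worker(name: str, params: dict[str, Any] | None = None) -> Worker:
    """Instantiate a registered worker by name with its config params."""
    if name not in WORKER_REGISTRY:
        raise KeyError(f"unknown worker {name!r}; see worker_catalogue()")
    factory = WORKER_REGISTRY[name]
    return Worker(factory.spec, factory.build(params or {}))


def worker_catalogue() -> dict[str, list[str]]:
    """Worker names grouped by category."""
    out: dict[str, list[str]] = {}
    for name, factory in sorted(WORKER_REGISTRY.items()):
        out.setdefault(factory.category, []).append(name)
    return out


def subworkflow_worker(name: str, graph: WorkflowGraph) -> Worker:
    """Wrap a nested workflow as a single node with no external ports."""
    spec = WorkerSpec(name)

    def fn(inputs: dict, context: RunContext) -> dict:
        from .engine import run_workflow

        run_workflow(graph, inputs={}, context=context)
        return {}

    return Worker(spec, fn)


# ---------------------------------------------------------------------------
# File I/O


@_register("File I/O", "read-sdf", [("path", "path")], [("molecules", "molecule-list")])
def _read_sdf(params):
    return lambda inputs, ctx: {"molecules": chem_io.read_sdf(inputs["path"])}


@_register("File I/O", "write-sdf", [("molecules", "molecule-list"), ("path", "path")], [("path", "path")])
def _write_sdf(params):
    return lambda inputs, ctx: {"path": chem_io.write_sdf(inputs["molecules"], inputs["path"])}


@_register("File I/O", "write-molfiles", [("molecules", "molecule-list"), ("dir", "path")], [("dir", "path")])
def _write_molfiles(params):
    def fn(inputs, ctx):
        chem_io.write_molfiles(inputs["molecules"], inputs["dir"])
        return {"dir": inputs["dir"]}

    return fn


@_register("File I/O", "read-cml", [("path", "path")], [("molecules", "molecule-list")])
def _read_cml(params):
    return lambda inputs, ctx: {"molecules": chem_io.read_cml(inputs["path"])}


@_register("File I/O", "write-cml", [("molecules", "molecule-list"), ("path", "path")], [("path", "path")])
def _write_cml(params):
    return lambda inputs, ctx: {"path": chem_io.write_cml(inputs["molecules"], inputs["path"])}


# ---------------------------------------------------------------------------
# SMILES tools


@_register("SMILES tools", "parse-smiles", [("smiles", "string")], [("molecules", "molecule-list")])
def _parse_smiles(params):
    def fn(inputs, ctx):
        records = [chem_io.parse_smiles(s) for s in str(inputs["smiles"]).split()]
        return {"molecules": chem_io.MoleculeSet(records, provenance="smiles-input")}

    return fn


@_register("SMILES tools", "write-smiles", [("molecules", "molecule-list")], [("smiles", "string")])
def _write_smiles(params):
    return lambda inputs, ctx: {"smiles": "\n".join(inputs["molecules"].smiles())}


# ---------------------------------------------------------------------------
# InChI


@_register("InChI", "inchi-generator", [("molecules", "molecule-list")], [("inchi", "string")])
def _inchi_gen(params):
    return lambda inputs, ctx: {
        "inchi": "\n".join(chem_io.to_inchi(r) for r in inputs["molecules"])
    }


@_register("InChI", "inchi-parser", [("inchi", "string")], [("molecules", "molecule-list")])
def _inchi_parse(params):
    def fn(inputs, ctx):
        records = [chem_io.parse_inchi(s) for s in str(inputs["inchi"]).splitlines() if s.strip()]
        return {"molecules": chem_io.MoleculeSet(records, provenance="inchi-input")}

    return fn


# ---------------------------------------------------------------------------
# Database I/O


@_register("Database I/O", "db-insert", [("molecules", "molecule-list"), ("path", "path")], [("count", "number")])
def _db_insert(params):
    def fn(inputs, ctx):
        with store.MoleculeStore(inputs["path"]) as st:
            ids = st.insert(inputs["molecules"])
        return {"count": len(ids)}

    return fn


@_register("Database I/O", "db-read", [("path", "path")], [("molecules", "molecule-list")])
def _db_read(params):
    def fn(inputs, ctx):
        with store.MoleculeStore(inputs["path"]) as st:
            return {"molecules": st.fetch()}

    return fn


@_register("Database I/O", "iterative-source", [("path", "path")], [("state_id", "string")])
def _iterative_source(params):
    state_id = params.get("state_id", "db")
    limit = int(params.get("limit", 100))
    query = params.get("query")

    def fn(inputs, ctx):
        st = store.MoleculeStore(inputs["path"])
        q = structure.SubstructureQuery(query) if query else None
        ctx.registry[state_id] = store.PageCursor(st, limit=limit, query=q)
        return {"state_id": state_id}

    return fn


@_register("Database I/O", "get-page", [], [("page", "molecule-list")])
def _get_page(params):
    state_id = params.get("state_id", "db")

    def fn(inputs, ctx):
        source = ctx.registry[state_id]
        page = source.next_page()
        items = [r.uid or r.canonical_smiles() for r in page] if hasattr(page, "records") else list(page)
        ctx.registry[f"{state_id}:last_page"] = items
        return {"page": page}

    return fn


@_register("Database I/O", "has-next", [("trigger", "molecule-list")], [("has_next", "string")])
def _has_next(params):
    state_id = params.get("state_id", "db")

    def fn(inputs, ctx):
        return {"has_next": ctx.registry[state_id].has_next()}

    return fn


# ---------------------------------------------------------------------------
# Molecular descriptors


@_register("Molecular descriptors", "compute-descriptors", [("molecules", "molecule-list")], [("table", "table")])
def _compute_descriptors(params):
    names = params.get("descriptors") or qsar.descriptor_names()

    def fn(inputs, ctx):
        prepared = chem_io.MoleculeSet(
            [structure.perceive_and_prepare(r) for r in inputs["molecules"]],
            provenance=inputs["molecules"].provenance,
        )
        tagged = qsar.tag_molecules(prepared)
        return {"table": qsar.compute_descriptors(tagged, names)}

    return fn


@_register("Molecular descriptors", "clean-vectors", [("table", "table")], [("table", "table")])
def _clean_vectors(params):
    policy = qsar.CleaningPolicy(**params) if params else qsar.CleaningPolicy()

    def fn(inputs, ctx):
        clean, report = qsar.clean_vectors(inputs["table"], policy)
        ctx.registry["last_removal_report"] = report
        return {"table": clean}

    return fn


@_register("Molecular descriptors", "write-descriptor-csv", [("table", "table"), ("path", "path")], [("path", "path")])
def _write_csv(params):
    return lambda inputs, ctx: {"path": qsar.write_csv(inputs["table"], inputs["path"])}


@_register("Molecular descriptors", "read-descriptor-csv", [("path", "path")], [("table", "table")])
def _read_csv(params):
    return lambda inputs, ctx: {"table": qsar.read_csv(inputs["path"])}


# ---------------------------------------------------------------------------
# Clustering


def _params_from(params: dict) -> art2a.ART2AParams:
    kwargs = {k: v for k, v in params.items() if k in art2a.ART2AParams.__dataclass_fields__}
    if "vigilance_range" in kwargs:
        kwargs["vigilance_range"] = tuple(kwargs["vigilance_range"])
    return art2a.ART2AParams(**kwargs)


@_register("Clustering", "art2a-classify", [("table", "table")], [("result", "clustering-result")])
def _art2a_classify(params):
    vigilance = float(params.get("vigilance", 0.7))
    p = _params_from(params)
    return lambda inputs, ctx: {"result": art2a.art2a_classify(inputs["table"], p, vigilance)}


@_register("Clustering", "art2a-scan", [("table", "table")], [("results", "clustering-result")])
def _art2a_scan(params):
    p = _params_from(params)
    return lambda inputs, ctx: {"results": art2a.art2a_scan(inputs["table"], p)}


@_register("Clustering", "write-cluster-xml", [("results", "clustering-result"), ("path", "path")], [("path", "path")])
def _write_cluster_xml(params):
    def fn(inputs, ctx):
        results = inputs["results"]
        if isinstance(results, art2a.ART2AResult):
            results = [results]
        return {"path": art2a.write_result_xml(results, inputs["path"])}

    return fn


# ---------------------------------------------------------------------------
# Miscellaneous


@_register("Miscellaneous", "identity", [("value", "string")], [("value", "string")])
def _identity(params):
    return lambda inputs, ctx: {"value": inputs["value"]}


@_register("Miscellaneous", "count-atoms", [("molecules", "molecule-list")], [("count", "number")])
def _count_atoms(params):
    return lambda inputs, ctx: {
        "count": sum(r.num_heavy_atoms for r in inputs["molecules"])
    }


@_register(
    "Miscellaneous",
    "substructure-filter",
    [("molecules", "molecule-list"), ("pattern", "string")],
    [("matching", "molecule-list"), ("non_matching", "molecule-list")],
)
def _substructure_filter(params):
    def fn(inputs, ctx):
        matching, non_matching = structure.substructure_filter(
            inputs["molecules"], inputs["pattern"]
        )
        return {"matching": matching, "non_matching": non_matching}

    return fn


@_register("Miscellaneous", "perceive-prepare", [("molecules", "molecule-list")], [("molecules", "molecule-list")])
def _perceive_prepare(params):
    def fn(inputs, ctx):
        molset = inputs["molecules"]
        return {
            "molecules": chem_io.MoleculeSet(
                [structure.perceive_and_prepare(r) for r in molset],
                provenance=molset.provenance,
            )
        }

    return fn


@_register("Miscellaneous", "tag-molecules", [("molecules", "molecule-list")], [("molecules", "molecule-list")])
def _tag(params):
    prefix = params.get("prefix", "m-")
    return lambda inputs, ctx: {"molecules": qsar.tag_molecules(inputs["molecules"], prefix=prefix)}


@_register("Miscellaneous", "validate-atom-types", [("molecules", "molecule-list"), ("dir", "path")], [("dir", "path")])
def _validate(params):
    def fn(inputs, ctx):
        report = structure.validate_atom_types(inputs["molecules"])
        report.write(inputs["dir"])
        ctx.registry["last_atom_type_report"] = report
        return {"dir": inputs["dir"]}

    return fn


@_register("Miscellaneous", "fail-if-true", [("flag", "string")], [("flag", "string")])
def _fail_if_true(params):
    return lambda inputs, ctx: {"flag": fail_if_true(inputs["flag"])}


@_register("Miscellaneous", "read-rxn", [("path", "path")], [("reaction", "reaction")])
def _read_rxn(params):
    return lambda inputs, ctx: {"reaction": enumeration.read_rxn(inputs["path"])}


@_register(
    "Miscellaneous",
    "enumerate-reaction",
    [("reaction", "reaction"), ("reactants", "molecule-list")],
    [("products", "molecule-list")],
)
def _enumerate(params):
    positions = params.get("positions")  # list of lists of uid per position

    def fn(inputs, ctx):
        rx = inputs["reaction"]
        pool = {r.uid: r for r in inputs["reactants"]}
        sets = []
        groups = positions or _group_by_prefix(pool, rx)
        for name, uids in zip(rx.position_names(), groups):
            molset = chem_io.MoleculeSet([pool[u] for u in uids])
            sets.append(enumeration.ReactantSet(name, molset))
        return {"products": enumeration.enumerate_products(rx, sets)}

    return fn


def _group_by_prefix(pool: dict, rx) -> list[list[str]]:
    # reactants tagged "R1-..", "R2-.." are routed to their position
    return [
        sorted(u for u in pool if u.startswith(f"{name}-"))
        for name in rx.position_names()
    ]


@_register("Miscellaneous", "enumeration-report", [("products", "molecule-list"), ("dir", "path")], [("dir", "path")])
def _enum_report(params):
    def fn(inputs, ctx):
        enumeration.enumeration_report(inputs["products"], inputs["dir"])
        return {"dir": inputs["dir"]}

    return fn
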