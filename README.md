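# chemflow

Composable, typed cheminformatics workers for desk-scale molecule pipelines:
chemical file I/O, topological substructure filtering, atom-type validation,
QSAR descriptor vectors with pre-clustering cleaning rules, ART 2-A
open-categorical clustering, generic (Markush) reaction enumeration, and
chunked iteration over a single-file molecule store. Pipelines run either as
plain Python or as declarative YAML workflow configs on the `chemflow` CLI.

It is aimed at scientists who process compound collections in repeatable
steps — filter, curate, describe, cluster, enumerate — and want those steps
as small reusable building blocks with explicit, type-checked data flow
rather than one-off scripts.

## What's inside

**Dataflow engine.** A worker is a function with named, semantically typed
input/output ports (`molecule-list`, `string`, `number`, `table`, `path`,
…). Workers wire into acyclic workflow graphs; every edge is type-checked
before anything runs. For large inputs the engine offers two equivalent loop
constructs over paged sources: a native FOR-style loop, and the classic
fail/retry emulation in which the loop body ends in a *has-next →
fail-if-true* chain whose failure signal triggers a re-run of the nested
workflow, one page per attempt. Both process each item exactly once in
⌈n/p⌉ body runs, and the tests hold them to identical traversals.

**ART 2-A clustering.** The core analysis algorithm is adaptive-resonance
clustering for analog vectors (Carpenter–Grossberg–Rosen style). Inputs are
contrast-enhanced and unit-normalized; the winning prototype **w** is the one
maximizing the dot product **w·x**, and the *vigilance* ρ ∈ (0, 1) decides
membership: if **w·x** ≥ ρ the input joins the cluster and the prototype
learns

&nbsp;&nbsp;&nbsp;&nbsp;**w** ← normalize(η·**x** + (1 − η)·**w**),

otherwise the input seeds a new cluster. No cluster count is fixed in
advance; scanning ρ over a range yields a resolution hierarchy, and cluster
*occupancies* per source collection quantify chemical-space overlap between
libraries. The estimator follows the scikit-learn API (`ART2AClassifier`
with `fit`/`fit_predict`, `labels_`, `cluster_centers_`).

**Descriptor pipeline.** Molecules are prepared (atom typing against a
curated valence catalogue, implicit hydrogens, Hückel-style aromaticity),
tagged with unique identifiers, and mapped to named numeric descriptor
components (20+ registered descriptors: constitutional counts, topological
indices, partial-charge summaries, ring/chain measures). Cleaning removes
constant components (min = max), components with too many missing values,
and rows carrying NaN/Infinity — iterated to a fixpoint so cleaning is
idempotent — before scaling each component to [0, 1] for clustering.

**Markush enumeration.** A generic reaction drawn with R-group placeholders
(R1..Rk) plus one reactant list per position enumerates the full cartesian
product of fragment grafts onto the product skeleton: 2 positions × 3
reactants each → 9 products. Product identity is canonical SMILES;
duplicates collapse with a recorded multiplicity.

## Worked example

```python
import chemflow as cf

mols = cf.gen_molecules(40, seed=7)                      # synthetic library
matching, rest = cf.substructure_filter(mols, "c1ccccc1")
print(f"{len(matching)} of {len(mols)} molecules contain a benzene ring")

prepared = cf.MoleculeSet([cf.perceive_and_prepare(r) for r in mols])
tagged = cf.tag_molecules(prepared)
table = cf.compute_descriptors(
    tagged, ["atom_count", "ring_count", "tpsa", "clogp", "bertz_ct"]
)
clean, report = cf.clean_vectors(table)
scaled = cf.scale_unit_interval(clean)

params = cf.ART2AParams(
    scale_to_unit_interval=False, seed=7, vigilance_range=(0.5, 0.9, 0.1)
)
for res in cf.art2a_scan(scaled, params):
    print(f"vigilance {res.vigilance:.1f}: {res.n_clusters} clusters "
          f"({res.epochs_run} epochs, {res.converged_by})")
```

Output:

```
4 of 40 molecules contain a benzene ring
vigilance 0.5: 3 clusters (3 epochs, prototype-similarity)
vigilance 0.6: 5 clusters (2 epochs, prototype-similarity)
vigilance 0.7: 6 clusters (3 epochs, assignment-stability)
vigilance 0.8: 7 clusters (2 epochs, prototype-similarity)
vigilance 0.9: 11 clusters (2 epochs, assignment-stability)
```

Four of the forty synthetic molecules carry a benzene ring; the descriptor
table survives cleaning intact (all cells finite, no constant component);
and the vigilance scan shows the expected behavior of open-categorical
clustering — the cluster count grows monotonically as the similarity demanded
for membership rises.

The same pipelines run from the shell; see `docs/examples/`:

```bash
chemflow fixtures molecules -n 20 --seed 7 -o mols.sdf
chemflow run docs/examples/substructure_search.yaml \
    --in reader.path=mols.sdf --in 'filter.pattern=c1ccccc1' \
    --in matched.dir=out/matching --in rest.path=out/non_matching.cml \
    --out out
chemflow workers-list
```

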