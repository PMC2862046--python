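# Methods

This note documents the models, conventions and numerical choices behind
chemflow's modules, what the synthetic-data generators do and do not
emulate, and the design decisions taken where more than one reasonable
reading existed.

## Dataflow engine

A workflow is a directed acyclic graph of workers. Ports carry a semantic
type from a registered vocabulary (`molecule-list`, `string`, `number`,
`table`, `path`, plus registered extras such as `clustering-result` and
`reaction`); an edge connecting mismatched types is rejected at validation
time, before any node runs. Shared run state (page cursors, last reports)
lives in an explicit string-keyed registry scoped to one `RunContext`, never
in module globals.

**Loop semantics.** Two constructs iterate a body over a paged source:

* *native loop*: `while source.has_remaining(): body(source.next_page())`;
* *fail/retry emulation*: the body is a nested workflow ending in a
  has-next → fail-if-true chain; fail-if-true raises a loop-continue signal
  whenever pages remain, and the engine's retry mechanism re-runs the nested
  workflow, one page per attempt.

Both are exposed because the emulation is the historically interesting
construct while the native loop is what a user should reach for; the test
suite asserts they produce identical page traversals. Decisions fixed here:
the has-next check runs *before* the first body execution, so an empty
source executes the body zero times (FOR-loop semantics); boolean text flags
are compared case-insensitively after whitespace trimming; a failed loop
attempt's partial outputs are discarded — only the page-cursor advance
survives, which is exactly what makes the retry semantics equivalent to a
loop. No node ever executes more than `1 + max_retries` times; exhausting
the budget raises an error naming the node and the pages left.

## Molecule records and formats

Molecules travel as an RDKit graph plus a string property map and a `uid`
tag. Canonical SMILES is the molecule identity everywhere (deduplication,
store round-trips, product identity). Formats: MDL SDF/Molfile **V2000
only**, SMILES/SMARTS, InChI, and a CML subset restricted to
`molecule`/`atomArray`/`bondArray`/`property` elements (unsupported elements
are skipped with a logged warning). Readers are per-record fault-tolerant: a
corrupt SDF block becomes a logged rejection, never a run abort, because
realistic inputs are large and imperfect. One molecule per record; lists are
`MoleculeSet`s that preserve input order across read → process → write.

## Atom typing and preparation

An atom type is *recognized* when the element appears in a curated
common-organic catalogue (H, B, C, N, O, F, Si, P, S, Cl, Se, Br, I) **and**
its (total valence, formal charge) pair is listed for that element — e.g.
N(3,0), N(4,+1), S(2/4/6,0). Everything else — metals, heavy elements,
exotic valences — is *unknown*, which is reported data rather than an error:
missing atom types are a systematic feature of public compound collections
and an important up-front filter before descriptor calculation.
Aromaticity uses RDKit's default electron-count (Hückel 4n+2 style) ring
model; the model name is recorded in the report metadata. The audit report
writes an ids file, a per-atom detail file and a CSV of totals; its printed
percentage is **truncated** (not rounded) at two decimals, matching the
convention of the audit reports this reproduces (1035/12367 → 8.36).

Substructure matching is graph-topological — element, bond order,
aromaticity; charge expressible in the pattern; stereo-insensitive.
Patterns compile as SMARTS first, falling back to SMILES. The test suite
checks the filter partition against an independent VF2
subgraph-monomorphism matcher (networkx) on queries where SMARTS and plain
graph semantics coincide (uncharged, explicit aromaticity and bond orders).

## Descriptor vectors and cleaning

Tagging assigns `m-` + zero-padded counter uids (prefix configurable),
preserving existing tags and refusing duplicates. The descriptor registry
holds 20+ descriptors spanning constitutional counts, ring/chain measures,
topological indices and Gasteiger partial-charge summaries; a descriptor may
emit several named components. A descriptor failure on one molecule yields
NaN cells plus a log entry. The table is a pandas DataFrame (index = uid,
columns in selection order); CSV serialization uses the header contract
`uid,<components...>`, `%.17g` cells, and the tokens `NaN` / `Infinity` /
`-Infinity`, so round-trips are lossless well past 12 significant digits.

Cleaning policy (defaults in parentheses): drop components whose finite
values satisfy min = max (on), drop components whose missing fraction
exceeds `component_missing_fraction_max` (0.1), then drop rows containing
NaN (on) or Infinity (on) or exceeding `row_missing_fraction_max` (0.0).
Columns are examined before rows so one broken component does not condemn
every molecule; the two passes repeat until a fixpoint, which is what makes
cleaning idempotent (a row removal can newly render a column constant).
Removing every row or every column is an explicit error. Scaling to [0, 1]
is per component (affine min→0, max→1); per-component rather than
per-vector scaling was chosen because cleaning already guarantees
non-constant components, making the map well defined.

## ART 2-A

The standard ART 2-A variant is implemented:

1. *Preprocess*: unit-normalize each input; zero components below the
   contrast threshold θ (default 1/√dim, the canonical uniform-vector
   level; θ = 0 disables enhancement) and renormalize. If enhancement would
   annihilate a vector it is kept unenhanced rather than lost.
2. *Choice*: winner = prototype with maximal dot product; ties break to the
   lowest cluster index.
3. *Vigilance test*: winner activation ≥ ρ → commit and learn
   `w ← normalize(η·x + (1−η)·w)` with learning rate η (default 0.1);
   otherwise seed a new cluster with prototype x.
4. *Convergence*: after each epoch, stop if assignments are unchanged
   (assignment-stability) or if every prototype's dot product with its
   previous-epoch self is at least the required similarity (default 0.99,
   prototype-similarity); otherwise continue to the epoch limit (100) or
   time limit (60 s), which still yield valid, flagged results.

The convergence wording this follows deliberately inverts an ambiguous
formulation sometimes seen ("scalar product … less than the required
similarity"): the dot product of successive near-identical unit prototypes
approaches 1, so halting when it is *small* would stop on maximal change.
We converge when it is *large* (≥ required similarity) and document the
discrepancy here rather than guess at historical behavior.

Presentation order: *deterministic-random* is one seeded shuffle reused
every epoch; *random-random* reshuffles each epoch from the run seed. Both
are bit-reproducible given the same data, parameters and seed. Clusters
left empty by reassignment are compacted out at the end, so every reported
cluster is non-empty and prototypes match `range(n_clusters)`. Results
serialize to gzip-compressed XML (`art2a-run → params, result* →
assignment*, class-vector*`, `%.17g` numbers) and round-trip exactly.
Successive top-down clustering re-runs the scan inside each cluster's
member subset to a configurable depth (default 2), skipping clusters
smaller than a minimum size.

Occupancy analysis counts, per (cluster, source label), the fraction of
that source's molecules landing in the cluster; fractions per source sum
to 1 across clusters.

## Markush enumeration

`read_rxn` accepts MDL RXN V2000 with `R#` pseudo-atoms; every product-side
label must appear on the reactant side, exactly one product template is
required, and a template without placeholders is rejected. Each reactant
fragment designates exactly one attachment atom (an `attachment_atom`
property, or a single dummy atom whose neighbor is the attachment); it
replaces the R# pseudo-atom, bonding to the skeleton anchor with the bond
order drawn in the template. Multi-attachment R-groups and variable bond
orders are out of scope. Enumeration is the cartesian product over
positions in lexicographic order (deterministic output); a combination
whose graft cannot be sanitized (valence violation) is skipped and logged;
duplicates by canonical SMILES collapse with a multiplicity count, so
`|products| ≤ ∏|set_i|` with equality for pairwise-distinct chemistry.

## Molecule store

A single-file SQLite database stands in for a client/server chemistry
cartridge at desk scale. Paging always orders by the monotone integer id —
LIMIT/OFFSET without an ORDER BY is nondeterministic, so the ordering is
fixed as part of the contract. Substructure queries scan the store with an
optional pattern-fingerprint prefilter that is superset-safe (it only
removes guaranteed non-matches; every survivor is verified by the full
matcher), so query results are provably identical to filtering the full
contents; LIMIT/OFFSET then page over the matching rows.

## Synthetic data

`gen_molecules` assembles molecules from a fixed vocabulary of ~30
valence-safe scaffolds and substituents (0–3 substitutions, junctions
consume implicit hydrogens, failed junctions are skipped), guaranteeing
parseable, sanitizable outputs; `contaminate_metals` grafts one
catalogue-absent metal atom into an exact count of molecules for audit
tests. The generator is deterministic per seed. It emulates small organic
screening-library members, not realistic drug-likeness distributions —
passing tests demonstrate pipeline correctness, not chemical realism.

`gen_vector_clouds` builds cosine-separable labeled clouds: orthogonal
non-negative centroids on disjoint coordinate blocks, uniform non-negative
noise (amplitude 0.12), rows unit-normalized; the within-cluster (> 0.95)
and between-cluster (< 0.5) cosine bounds are verified post hoc and the
cloud is resampled until they hold. Label-recovery tests run at vigilance
0.7 with contrast enhancement off — any ρ strictly between the two cosine
bounds separates the clouds, and 0.7 sits comfortably between them. These
clouds emulate the geometry descriptor vectors present to ART 2-A, not the
correlated, heavy-tailed structure of real descriptor tables.

`gen_reaction_fixture` builds a k-carbon-chain skeleton bearing one R-group
per carbon and draws per-position fragments without replacement from
disjoint vocabulary slices, so distinct combinations give distinct products
and the count law `∏ sizes` is exact.

## Problem sizes and limitations

Default verification sizes: 100 molecules × 10 queries for the
substructure-oracle comparison, 20 seeds × 20 points for label recovery,
20 seeds × 9-step vigilance scans for monotonicity, 25 (n, p) combinations
for loop exactness, 30–200 molecules for round-trip and store suites —
desk-scale sizes chosen so the whole suite runs in seconds while still
exercising every pathway end to end. Known limitations: V2000 only; the
atom-type catalogue is deliberately minimal (it flags, it does not
enumerate, metal chemistry); stereochemistry is preserved by RDKit but not
part of matching or identity guarantees; the store is not meant for
million-molecule benchmarking.
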