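# Topological substructure search over an SDF:
# matching molecules -> individual Molfiles, non-matching -> one CML file.
#
#   chemflow run docs/examples/substructure_search.yaml \
#       --in reader.path=molecules.sdf \
#       --in filter.pattern='c1ccccc1' \
#       --in matched.dir=out/matching \
#       --in rest.path=out/non_matching.cml \
#       --out out
nodes:
  reader:
    worker: read-sdf
  filter:
    worker: substructure-filter
  matched:
    worker: write-molfiles
  rest:
    worker: write-cml
edges:
  - reader.molecules -> filter.molecules
  - filter.matching -> matched.molecules
  - filter.non_matching -> rest.molecules
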