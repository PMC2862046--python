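# Descriptor-vector pipeline: prepare molecules, tag them with uids,
# compute a descriptor selection, clean the vectors, write the CSV.
#
#   chemflow run docs/examples/descriptor_pipeline.yaml \
#       --in reader.path=molecules.sdf --in csv.path=out/descriptors.csv \
#       --out out
nodes:
  reader:
    worker: read-sdf
  descriptors:
    worker: compute-descriptors
    params:
      descriptors: [atom_count, ring_count, molecular_weight, tpsa, clogp]
  clean:
    worker: clean-vectors
  csv:
    worker: write-descriptor-csv
edges:
  - reader.molecules -> descriptors.molecules
  - descriptors.table -> clean.table
  - clean.table -> csv.table
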