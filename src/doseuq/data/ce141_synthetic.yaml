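# Example run: 141Ce ingestion with the packaged cerium model and a
# three-phantom synthetic SAF ensemble.
nuclide: Ce-141
model: builtin:cerium
phantoms:
  synthetic:
    n_phantoms: 3
    mass_gsd: 1.15
    saf_gsd: 1.30
    seed: 314159
weights: builtin:icrp103
n: 500
seed: 1
t_d: 18262.5
targets: default
out_dir: results
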