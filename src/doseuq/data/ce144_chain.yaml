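# 144Ce decay chain: 144Ce -> {144mPr, 144Pr} -> 144Nd (treated as stable,
# T1/2 = 2.29e15 y). Members are topologically ordered, parent first.
#
# provenance: the cerium emission lines are the published evaluation values;
# the Ce-144 branching fractions and ALL praseodymium emission data below are
# provenance PLACEHOLDERS taken from standard decay-data compilations and are
# meant to be overridden by users with access to an evaluated nuclear
# database. Chain arithmetic in the test suite uses toy chains with stated
# branchings, never these placeholders.
members:
  - name: Ce-144
    half_life_days: 284.9
    emissions:
      - {type: electron, energy_MeV: 0.050, yield: 0.192}
      - {type: electron, energy_MeV: 0.066, yield: 0.039}
      - {type: electron, energy_MeV: 0.091, yield: 0.769}
      - {type: photon, energy_MeV: 0.041, yield: 0.0032}
      - {type: photon, energy_MeV: 0.080, yield: 0.014}
      - {type: photon, energy_MeV: 0.134, yield: 0.1083}
    progeny:
      - {name: Pr-144m, branching: 0.0098}   # placeholder
      - {name: Pr-144, branching: 0.9902}    # placeholder
  - name: Pr-144m
    half_life_days: 0.005                    # 7.2 min
    emissions:                               # placeholders (conversion e-, gamma)
      - {type: electron, energy_MeV: 0.047, yield: 0.64}
      - {type: photon, energy_MeV: 0.059, yield: 0.007}
    progeny:
      - {name: Pr-144, branching: 0.9993}    # isomeric transition, placeholder
      # remaining 0.0007 beta branch ends in stable Nd-144
  - name: Pr-144
    half_life_days: 0.012                    # 17.28 min
    emissions:                               # placeholders
      - {type: electron, energy_MeV: 1.21, yield: 0.979}
      - {type: electron, energy_MeV: 0.895, yield: 0.0105}
      - {type: photon, energy_MeV: 0.6965, yield: 0.0134}
      - {type: photon, energy_MeV: 2.1856, yield: 0.0070}
    # Nd-144 treated as stable: no progeny.
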