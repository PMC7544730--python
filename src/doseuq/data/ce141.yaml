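# 141Ce decay data (line representation: mean beta energies with branch
# yields, principal gamma line). Yields are emissions per transformation.
name: Ce-141
half_life_days: 32.5
emissions:
  - {type: electron, energy_MeV: 0.129, yield: 0.70}
  - {type: electron, energy_MeV: 0.180, yield: 0.30}
  - {type: photon, energy_MeV: 0.145, yield: 0.48}
# The 141Pr ground state is stable: no radioactive progeny.
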