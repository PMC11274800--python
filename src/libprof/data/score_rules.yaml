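# Default range rules for the de novo score.
#
# Intervals are mean +/- 1 SD of the seven descriptors over a reference set
# of DNMT1-active compounds; regenerate with
# libprof.profiling.build_score_rules(actives) for your own active set.
# The penalty patterns veto nucleoside-like molecules (ribofuranose linked
# to an aromatic N-heterocycle), since the goal is non-nucleoside chemistry.
ranges:
  mw: [250.0, 600.0]
  hbd: [0.0, 4.0]
  hba: [2.0, 10.0]
  logp: [0.0, 5.0]
  esol: [-6.0, -1.0]
  sascore: [1.0, 4.5]
  tpsa: [40.0, 160.0]
penalty_patterns:
  # ribose/deoxyribose attached to an aromatic nitrogen (nucleoside core)
  - "[nX3]C1OC(CO)C(O)C1"
  - "[nX3]C1OC(CO)CC1"
penalty_value: 1.0
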