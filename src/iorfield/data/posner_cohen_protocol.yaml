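# Double-cueing trial layout: peripheral cue/target boxes at Nodes 25 and
# 75, fixation at Node 50 (also the catch-trial target location), expectation
# signals at every possible target location.
ctoas: [0, 50, 100, 200, 300, 500]
cue_node: 25
uncued_target_node: 75
catch_node: 50
expectation_nodes: [25, 50, 75]
cue:
  I_max: "40"
  sigma: "8"
  duration_ms: "50"
target:
  I_max: "60"
  sigma: "8"
fixation:
  node: 50
  I_max: "10"
  sigma: "4"
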