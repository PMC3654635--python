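{
  "synthetic_demo_family.tsv": "a59fc4ce2ed875998cf528c91d92a8e2cf7dd0810c4c31a785860c816c166eaa",
  "table1_markers.tsv": "c2579512ddd51539eb9795336c0178fb10d94c5f5ea08b7b8945ca0ea64b4859",
  "table2_cycles.tsv": "b80d6ab41ec6366d04224a9c333ffdf27ee1722ddbc8fa21239b544c42a63237",
  "table3_combinations.tsv": "0acb29121c0d9f468de9aec3e95c9c7567287e80714f143ffc3be4292a0918b3"
}
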