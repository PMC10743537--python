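{
  "strand1_units": ["G1", "C2", "G3", "T4", "T5", "G6", "T7", "C8", "G9", "C10"],
  "strand2_units": ["G11", "C12", "G13", "A14", "C15", "A16", "A17", "C18", "G19", "C20"],
  "nick_after": "T5",
  "nick_adjacent_set": ["T4", "T5", "G6", "T7", "A14", "C15", "A16", "A17"]
}
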