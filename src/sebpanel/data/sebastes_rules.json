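{
  "mentella": {"SEB29": "CC", "SEB39": "CC", "SEB25": "GG"},
  "norvegicusA": {"SEB29": "CC", "SEB39": "TT", "SEB25": "AA"},
  "norvegicusB": {"SEB29": "CC", "SEB39": "TT", "SEB25": "GG"},
  "viviparus": {"SEB29": "TT", "SEB39": "TT", "SEB25": "GG"}
}
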