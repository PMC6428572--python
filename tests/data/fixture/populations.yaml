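populations:
  POP1:
    latitude: 36.0
    longitude: -9.0
  POP2:
    latitude: 42.5
    longitude: -0.25
  POP3:
    latitude: 49.0
    longitude: 8.5
  POP4:
    latitude: 55.5
    longitude: 17.25
  POP5:
    latitude: 62.0
    longitude: 26.0
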