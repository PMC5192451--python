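{
  "cytosol": {
    "ph": 7.0,
    "ionic_strength_M": 0.15,
    "temperature_K": 298.15
  }
}
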