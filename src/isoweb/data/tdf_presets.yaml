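# Rainbow-trout TDF presets used in the model grid.
# TDF1 is the study-calculated white-muscle TDF; TDF2-TDF5 are published
# rainbow-trout / salmonid values. Units are per-mil (permil).
TDF1:
  mean_dC: 0.49
  sd_dC: 4.7
  mean_dN: 4.43
  sd_dN: 1.32
  provenance: calculated
TDF2:
  mean_dC: 0.8
  sd_dC: 1.1
  mean_dN: 3.0
  sd_dN: 2.6
  provenance: published
TDF3:
  mean_dC: 0.91
  sd_dC: 1.04
  mean_dN: 3.41
  sd_dN: 0.2
  provenance: published
TDF4:
  mean_dC: 1.85
  sd_dC: 0.0
  mean_dN: 2.54
  sd_dN: 0.0
  provenance: published
TDF5:
  mean_dC: 2.8
  sd_dC: 1.5
  mean_dN: 5.14
  sd_dN: 1.35
  provenance: published
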