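name: SRM
aerobic: true
carbon_uptake: 10.0
amino_acid_uptake: 0.1
carbon_exchanges: []
nitrogen_exchanges: []
sulfur_exchanges: []
amino_acid_exchanges: []
free_exchanges:
- EX_co2_e
- EX_h2o_e
- EX_h_e
oxygen_exchange: EX_o2_e
exchange_overrides:
  EX_sucr_e:
  - -5.0
  - 1000.0
atp_maintenance: ATPM
atp_settings: null
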