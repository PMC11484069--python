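# Pig preset: Yorkshire swine, 40% TBSA full-thickness burn model.
species: pig
inherit: base
subject_defaults: {weight: 31.7, weight_sd: 4.2, tbsa: 0.40, tbsa_sd: 0.0, hct0: 0.33}
protocol: {uo_band_low: 1.0, uo_band_high: 1.5, per_kg_band: true,
           horizon_h: 24.0, start_delay_h: 0.0, fixed_rate: 500.0}
overrides:
  - {name: co0_perkg, value: 0.10}
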