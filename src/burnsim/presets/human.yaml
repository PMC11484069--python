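# Human preset: adult burn-ICU patient. Overlays base.yaml.
species: human
inherit: base
subject_defaults: {weight: 85.0, weight_sd: 18.0, tbsa: 0.42, tbsa_sd: 0.18, hct0: 0.40}
protocol: {uo_band_low: 30.0, uo_band_high: 50.0, per_kg_band: false,
           horizon_h: 24.0, start_delay_h: 0.0, fixed_rate: 500.0}
overrides: []
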