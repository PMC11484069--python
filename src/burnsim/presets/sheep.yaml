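# Sheep preset: adult sheep, 40% TBSA, 48 h resuscitation started 1 h post-burn.
species: sheep
inherit: base
subject_defaults: {weight: 40.0, weight_sd: 0.0, tbsa: 0.40, tbsa_sd: 0.0, hct0: 0.32}
protocol: {uo_band_low: 1.0, uo_band_high: 2.0, per_kg_band: true,
           horizon_h: 48.0, start_delay_h: 1.0, fixed_rate: 500.0}
overrides:
  - {name: co0_perkg, value: 0.09}
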