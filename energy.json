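{
  "annual_fixture_saving_kwh": 474.5,
  "annual_fixture_saving_kwh_reported": 475.0,
  "fractional_saving_pct": 9,
  "hourly_fraction_saving_pct": 4.54,
  "lifetime_consumption_kwh": 29250.0,
  "scenario": {
    "baseline_photoperiod_h": 22.0,
    "currency": "\u00a3",
    "delta_h": 2.0,
    "fixture_area_sqft": 8.0,
    "fixture_power_kw": 0.65,
    "reduced_photoperiod_h": 20.0,
    "tariff_per_kwh": 0.22
  }
}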