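# Fixture formulary F1.
# Values are round numbers chosen for arithmetic transparency in tests.
# They are NOT clinical content and must never be used for prescribing.
version: F1
drugs:
  - {name: morphine, route: oral, renal_risk: true}
  - {name: morphine, route: subcutaneous, renal_risk: true}
  - {name: oxycodone, route: oral}
  - {name: oxycodone, route: subcutaneous}
  - {name: codeine, route: oral, renal_risk: true}
  - {name: alfentanil, route: subcutaneous, renal_risk: false}
  - {name: diamorphine, route: subcutaneous, renal_risk: true}
  - {name: hydromorphone, route: oral}
  - {name: methadone, route: oral, supported: false}
  - {name: fentanyl, route: transdermal}
factors:
  - {drug: morphine, route: oral, ome_per_unit: 1}
  - {drug: morphine, route: subcutaneous, ome_per_unit: 2}
  - {drug: oxycodone, route: oral, ome_per_unit: 2}
  - {drug: oxycodone, route: subcutaneous, ome_per_unit: 4}
  - {drug: codeine, route: oral, ome_per_unit: 0.1}
  - {drug: alfentanil, route: subcutaneous, ome_per_unit: 30}
  - {drug: diamorphine, route: subcutaneous, ome_per_unit: 3}
  - {drug: hydromorphone, route: oral, ome_per_unit: 5}
patch_tables:
  fentanyl:
    - {strength: 12, ome_low: 30, ome_high: 60}
    - {strength: 25, ome_low: 60, ome_high: 90}
    - {strength: 50, ome_low: 90, ome_high: 150}
    - {strength: 75, ome_low: 150, ome_high: 210}
    - {strength: 100, ome_low: 210, ome_high: 270}
defaults:
  breakthrough_divisor: 6
  egfr_warning_threshold: 30
  practical_increments:
    oral: 2.5
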