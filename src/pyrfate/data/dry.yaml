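schema_version: 1
name: dry
description: >
  Dry (winter, ~5 C) moisture regime: measured hourly transport and
  elimination rates for pyrene in an air/water/sediment system.
states:
  - {label: volatilization, kind: absorbing}
  - {label: biodegradation, kind: absorbing}
  - {label: water, kind: transient}
  - {label: sediment, kind: transient}
pathways:
  - name: sorption
    source: water
    destination: sediment
    units: ng/mL/h
    segments:
      - {start: 0, end: null, rate: 0.0164}
  - name: desorption
    source: sediment
    destination: water
    units: ng/g/h
    segments:
      - {start: 0, end: 36, rate: 0.0278}
      - {start: 36, end: null, rate: 0.002}
  - name: biodegradation
    source: sediment
    destination: biodegradation
    units: ng/g/h
    segments:
      - {start: 0, end: 12, rate: 0.0076}
      - {start: 12, end: 72, rate: 0.0116}
      - {start: 72, end: null, rate: 0.0061}
  - name: volatilization
    source: water
    destination: volatilization
    units: ng/mL/h
    segments:
      - {start: 0, end: null, rate: 0.0011}
initial: {water: 101.24}
t0: 1.0
threshold: 0.01
interpretation: probability
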