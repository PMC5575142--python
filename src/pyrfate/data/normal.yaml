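schema_version: 1
name: normal
description: >
  Average (spring/autumn, ~13 C) moisture regime: measured hourly transport
  and elimination rates for pyrene in an air/water/sediment system.
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
      - {start: 0, end: null, rate: 0.0284}
  - name: desorption
    source: sediment
    destination: water
    units: ng/g/h
    segments:
      - {start: 0, end: 36, rate: 0.0538}
      - {start: 36, end: null, rate: 0.0031}
  - name: biodegradation
    source: sediment
    destination: biodegradation
    units: ng/g/h
    segments:
      - {start: 0, end: 18, rate: 0.0098}
      - {start: 18, end: null, rate: 0.0135}
  - name: volatilization
    source: water
    destination: volatilization
    units: ng/mL/h
    segments:
      - {start: 0, end: null, rate: 0.0186}
initial: {water: 102.05}
t0: 1.0
threshold: 0.01
interpretation: probability
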