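schema_version: 1
name: wet
description: >
  Wet (summer, ~25 C) moisture regime: measured hourly transport and
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
      - {start: 0, end: 48, rate: 0.0578}
      - {start: 48, end: null, rate: 0.0231}
  - name: desorption
    source: sediment
    destination: water
    units: ng/g/h
    segments:
      - {start: 0, end: 18, rate: 0.0775}
      - {start: 18, end: null, rate: 0.0051}
  - name: biodegradation
    source: sediment
    destination: biodegradation
    units: ng/g/h
    segments:
      - {start: 0, end: 12, rate: 0.021}
      - {start: 12, end: 48, rate: 0.0373}
      - {start: 48, end: null, rate: 0.0227}
  - name: volatilization
    source: water
    destination: volatilization
    units: ng/mL/h
    segments:
      - {start: 0, end: null, rate: 0.0542}
initial: {water: 101.38}
t0: 1.0
threshold: 0.01
interpretation: probability
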