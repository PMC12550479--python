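# Superfamily diagnostics from TSD and TIR signatures.
# Rules are evaluated in increasing priority number; the first rule whose
# conditions all hold assigns the label. Edit and pass via --rules to
# override without code changes.
rules:
  - name: Micron
    priority: 1
    micron_context: true       # (TA)n/(CA)n/(GT)n run adjacent to the element
  - name: CACTA
    priority: 2
    tsd_len: [2, 3]
    tir_prefix: "CACT[AG]"
  - name: Tc1/Mariner
    priority: 3
    tsd_exact: ["TA"]
  - name: PIF/Harbinger
    priority: 4
    tsd_exact: ["TAA", "TTA"]
  - name: hAT
    priority: 5
    tsd_len: [8, 8]
    tir_len: [5, 27]
  - name: Mutator
    priority: 6
    tsd_len: [8, 10]
micron:
  min_units: 5
  window: 20
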