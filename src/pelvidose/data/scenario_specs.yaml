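# The five collective-dose optimisation scenarios.
# Uniform effective doses for scenarios 2-4 correspond to the per-exam
# effective dose at the European DRL (KAP 3.0 Gy cm2), the Dutch target DRL
# (KAP 1.5 Gy cm2) and an optimised modern room, respectively.
scenarios:
  - id: 1
    label: national doses, national frequencies (baseline)
  - id: 2
    label: European DRL dose everywhere
    e_override_mSv: 0.52
  - id: 3
    label: Dutch target DRL dose everywhere
    e_override_mSv: 0.26
  - id: 4
    label: optimised hospital dose everywhere
    e_override_mSv: 0.095
  - id: 5
    label: national doses, Dutch frequency everywhere
    freq_reference_country: Netherlands-like
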