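farm_fractions:
- 0.0
- 0.1
- 0.2
- 0.3
- 0.4
attraction_levels:
- 1.0
- 5.0
- 15.0
movement_fractions:
- 0.08
regimes:
- strong_msy
- weak_open_access
layouts:
- one_large
- several_small
m_multipliers:
- 1.0
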