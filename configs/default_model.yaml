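W:
- - 0.0
  - 0.3
- - -1.2
  - 0.0
b_context:
  dark:
    E: 0.3
    I: 0.95
  light:
    E: 0.6
    I: 0.1
g_auditory:
  E: 0.6
  I: 1.0
g_visual:
  E: 1.0
  I: 0.0
nonlinearity:
  E:
    k_hi: 2.0
    k_lo: 0.2
    offset: 0.05
    theta: 1.0
  I:
    k_hi: 2.0
    k_lo: 0.1
    offset: 0.1
    theta: 1.0
populations:
- I
- E
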