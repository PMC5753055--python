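# Karplus parameterisations for 3J(HN-HA): J = A cos^2(phi + phase) + B cos(phi + phase) + C
# Units: A, B, C in Hz; phase in degrees.
default: vuister-bax-1993
sets:
  vuister-bax-1993:
    A: 6.51
    B: -1.76
    C: 1.60
    phase: -60.0
  pardi-1984:
    A: 6.4
    B: -1.4
    C: 1.9
    phase: -60.0
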