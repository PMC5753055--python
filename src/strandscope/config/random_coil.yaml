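# Random-coil chemical shifts (ppm) used as the CSD reference.
# The CF3-threonine stereoisomers (TFR, TFS) have no published coil values
# and are intentionally absent; CSDs for them are reported "no-reference".
name: wishart-style-coil-shifts
shifts:
  ALA: {HA: 4.32, CA: 52.5}
  VAL: {HA: 4.12, CA: 62.2}
  LEU: {HA: 4.34, CA: 55.1}
  SER: {HA: 4.47, CA: 58.3}
  THR: {HA: 4.35, CA: 61.8}
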