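connectivity:
  E->PV: true
  E->SST: true
  E->VIP: true
  PV->E: true
  PV->VIP: true
  SST->E: true
  SST->SST: true
  SST->VIP: true
  VIP->PV: true
  VIP->SST: true
  VIP->VIP: true
input_pos:
  bu_targets:
  - E
  - SST
  - VIP
  td_targets:
  - E
  - PV
  - SST
  - VIP
input_neg:
  bu_targets:
  - E
  - PV
  - SST
  - VIP
  td_targets:
  - E
  - SST
  - VIP
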