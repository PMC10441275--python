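units:
  rates: d-1
  concentrations: nmol L-1
  abundances: cells L-1
  quotas: nmol cell-1
  supply: nmol L-1 d-1
parameters:
  VmaxNO3Pro: 0.1
  VmaxNH4Pro: 1.2
  KNO3Pro: 45.0
  KNH4Pro: 8.0
  mPro: 0.12
  QNPro: 5.0e-07
  VmaxNO3Syn: 0.6
  VmaxNH4Syn: 1.0
  KNO3Syn: 15.0
  KNH4Syn: 51.0
  mSyn: 0.12
  QNSyn: 1.5e-06
  SNO3: 2.5
  SNH4: 7.5
initial:
  XPro: 25000000.0
  XSyn: 4000000.0
  NO3: 5.0
  NH4: 5.0
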