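# Default stationary-phase registry.
#
# Ordered catalogs of stationary-phase type names.  The order is load-bearing:
# it fixes the slot layout of the length-38 phase encoding and the ordering of
# the predicted-RI feature block, so changing it invalidates trained models.
# The non-polar catalog is closed (36 types); the polar catalog lists the 20
# most common standard polar phases plus a catch-all "Other polar" slot.
version: 1
nonpolar_types:
  - DB-1
  - DB-5
  - OV-1
  - OV-101
  - SE-30
  - SE-54
  - Squalane
  - HP-1
  - HP-5
  - DB-5MS
  - CP-Sil 5 CB
  - CP-Sil 8 CB
  - RTX-1
  - RTX-5
  - BP-1
  - BP-5
  - ZB-1
  - ZB-5
  - SPB-1
  - SPB-5
  - Ultra-1
  - Ultra-2
  - OV-73
  - SF-96
  - Apiezon L
  - Apiezon M
  - Methyl silicone
  - Phenyl methyl silicone
  - DB-1MS
  - HP-5MS
  - Elite-1
  - Elite-5
  - Petrocol DH
  - VF-1ms
  - VF-5ms
  - Polydimethyl siloxane
polar_types:
  - DB-WAX
  - Carbowax 20M
  - HP-20M
  - Supelcowax 10
  - HP-Innowax
  - CP-Wax 52 CB
  - BP-20
  - ZB-WAX
  - RTX-WAX
  - Stabilwax
  - FFAP
  - OV-351
  - DB-FFAP
  - Carbowax 1540
  - Carbowax 4000
  - PEG-20M
  - TC-WAX
  - AT-WAX
  - Innowax FSC
  - CAM
  - Other polar
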