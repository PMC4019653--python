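{
 "ERG": 1.0,
 "DRG": 0.0,
 "CycD": 0.0,
 "CycD_Kip": 0.0,
 "Rb": 0.06344644,
 "pRb": 0.2646586,
 "ppRb": 0.64052729,
 "E2F_Rb": 0.03136766,
 "E2F": 0.11074322,
 "pE2F": 1.91274509,
 "CycE": 0.20551059,
 "CycE_Kip": 0.07175489,
 "Kip1": 0.17929856,
 "CycA2": 0.00359163,
 "CycA1": 0.00097234,
 "CycA_Kip": 0.00029774,
 "CycB": 0.33991103,
 "actCycB": 0.1842725,
 "Wee1": 0.56037166,
 "Cdc25": 0.97259841,
 "Cdh1": 0.39138539,
 "Cdc20T": 0.94707155,
 "Cdc20A": 0.85150529,
 "IEP": 0.93640458,
 "TFAB": 0.34531744
}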