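name,provider
MaxAbsEStateIndex,rdkit
MaxEStateIndex,rdkit
MinAbsEStateIndex,rdkit
MinEStateIndex,rdkit
qed,rdkit
SPS,rdkit
MolWt,rdkit
HeavyAtomMolWt,rdkit
ExactMolWt,rdkit
NumValenceElectrons,rdkit
NumRadicalElectrons,rdkit
MaxPartialCharge,rdkit
MinPartialCharge,rdkit
MaxAbsPartialCharge,rdkit
MinAbsPartialCharge,rdkit
FpDensityMorgan1,rdkit
FpDensityMorgan2,rdkit
FpDensityMorgan3,rdkit
BCUT2D_MWHI,rdkit
BCUT2D_MWLOW,rdkit
BCUT2D_CHGHI,rdkit
BCUT2D_CHGLO,rdkit
BCUT2D_LOGPHI,rdkit
BCUT2D_LOGPLOW,rdkit
BCUT2D_MRHI,rdkit
BCUT2D_MRLOW,rdkit
AvgIpc,rdkit
BalabanJ,rdkit
BertzCT,rdkit
Chi0,rdkit
Chi0n,rdkit
Chi0v,rdkit
Chi1,rdkit
Chi1n,rdkit
Chi1v,rdkit
Chi2n,rdkit
Chi2v,rdkit
Chi3n,rdkit
Chi3v,rdkit
Chi4n,rdkit
Chi4v,rdkit
HallKierAlpha,rdkit
Ipc,rdkit
Kappa1,rdkit
Kappa2,rdkit
Kappa3,rdkit
LabuteASA,rdkit
PEOE_VSA1,rdkit
PEOE_VSA10,rdkit
PEOE_VSA11,rdkit
PEOE_VSA12,rdkit
PEOE_VSA13,rdkit
PEOE_VSA14,rdkit
PEOE_VSA2,rdkit
PEOE_VSA3,rdkit
PEOE_VSA4,rdkit
PEOE_VSA5,rdkit
PEOE_VSA6,rdkit
PEOE_VSA7,rdkit
PEOE_VSA8,rdkit
PEOE_VSA9,rdkit
SMR_VSA1,rdkit
SMR_VSA10,rdkit
SMR_VSA2,rdkit
SMR_VSA3,rdkit
SMR_VSA4,rdkit
SMR_VSA5,rdkit
SMR_VSA6,rdkit
SMR_VSA7,rdkit
SMR_VSA8,rdkit
SMR_VSA9,rdkit
SlogP_VSA1,rdkit
SlogP_VSA10,rdkit
SlogP_VSA11,rdkit
SlogP_VSA12,rdkit
SlogP_VSA2,rdkit
SlogP_VSA3,rdkit
SlogP_VSA4,rdkit
SlogP_VSA5,rdkit
SlogP_VSA6,rdkit
SlogP_VSA7,rdkit
SlogP_VSA8,rdkit
SlogP_VSA9,rdkit
TPSA,rdkit
EState_VSA1,rdkit
EState_VSA10,rdkit
EState_VSA11,rdkit
EState_VSA2,rdkit
EState_VSA3,rdkit
EState_VSA4,rdkit
EState_VSA5,rdkit
EState_VSA6,rdkit
EState_VSA7,rdkit
EState_VSA8,rdkit
EState_VSA9,rdkit
VSA_EState1,rdkit
VSA_EState10,rdkit
VSA_EState2,rdkit
VSA_EState3,rdkit
VSA_EState4,rdkit
VSA_EState5,rdkit
VSA_EState6,rdkit
VSA_EState7,rdkit
VSA_EState8,rdkit
VSA_EState9,rdkit
FractionCSP3,rdkit
HeavyAtomCount,rdkit
NHOHCount,rdkit
NOCount,rdkit
NumAliphaticCarbocycles,rdkit
NumAliphaticHeterocycles,rdkit
NumAliphaticRings,rdkit
NumAromaticCarbocycles,rdkit
NumAromaticHeterocycles,rdkit
NumAromaticRings,rdkit
NumHAcceptors,rdkit
NumHDonors,rdkit
NumHeteroatoms,rdkit
NumRotatableBonds,rdkit
NumSaturatedCarbocycles,rdkit
NumSaturatedHeterocycles,rdkit
NumSaturatedRings,rdkit
RingCount,rdkit
MolLogP,rdkit
MolMR,rdkit
AUTOCORR2D_001,autocorr2d:0
AUTOCORR2D_002,autocorr2d:1
AUTOCORR2D_003,autocorr2d:2
AUTOCORR2D_004,autocorr2d:3
AUTOCORR2D_005,autocorr2d:4
AUTOCORR2D_006,autocorr2d:5
AUTOCORR2D_007,autocorr2d:6
AUTOCORR2D_008,autocorr2d:7
AUTOCORR2D_009,autocorr2d:8
AUTOCORR2D_010,autocorr2d:9
AUTOCORR2D_011,autocorr2d:10
AUTOCORR2D_012,autocorr2d:11
AUTOCORR2D_013,autocorr2d:12
AUTOCORR2D_014,autocorr2d:13
AUTOCORR2D_015,autocorr2d:14
AUTOCORR2D_016,autocorr2d:15
AUTOCORR2D_017,autocorr2d:16
AUTOCORR2D_018,autocorr2d:17
AUTOCORR2D_019,autocorr2d:18
AUTOCORR2D_020,autocorr2d:19
AUTOCORR2D_021,autocorr2d:20
AUTOCORR2D_022,autocorr2d:21
AUTOCORR2D_023,autocorr2d:22
AUTOCORR2D_024,autocorr2d:23
AUTOCORR2D_025,autocorr2d:24
AUTOCORR2D_026,autocorr2d:25
AUTOCORR2D_027,autocorr2d:26
AUTOCORR2D_028,autocorr2d:27
AUTOCORR2D_029,autocorr2d:28
AUTOCORR2D_030,autocorr2d:29
AUTOCORR2D_031,autocorr2d:30
AUTOCORR2D_032,autocorr2d:31
AUTOCORR2D_033,autocorr2d:32
AUTOCORR2D_034,autocorr2d:33
AUTOCORR2D_035,autocorr2d:34
AUTOCORR2D_036,autocorr2d:35
AUTOCORR2D_037,autocorr2d:36
AUTOCORR2D_038,autocorr2d:37
AUTOCORR2D_039,autocorr2d:38
AUTOCORR2D_040,autocorr2d:39
AUTOCORR2D_041,autocorr2d:40
AUTOCORR2D_042,autocorr2d:41
AUTOCORR2D_043,autocorr2d:42
AUTOCORR2D_044,autocorr2d:43
AUTOCORR2D_045,autocorr2d:44
AUTOCORR2D_046,autocorr2d:45
AUTOCORR2D_047,autocorr2d:46
AUTOCORR2D_048,autocorr2d:47
AUTOCORR2D_049,autocorr2d:48
AUTOCORR2D_050,autocorr2d:49
AUTOCORR2D_051,autocorr2d:50
AUTOCORR2D_052,autocorr2d:51
AUTOCORR2D_053,autocorr2d:52
AUTOCORR2D_054,autocorr2d:53
AUTOCORR2D_055,autocorr2d:54
AUTOCORR2D_056,autocorr2d:55
AUTOCORR2D_057,autocorr2d:56
AUTOCORR2D_058,autocorr2d:57
AUTOCORR2D_059,autocorr2d:58
AUTOCORR2D_060,autocorr2d:59
AUTOCORR2D_061,autocorr2d:60
AUTOCORR2D_062,autocorr2d:61
AUTOCORR2D_063,autocorr2d:62
AUTOCORR2D_064,autocorr2d:63
AUTOCORR2D_065,autocorr2d:64
AUTOCORR2D_066,autocorr2d:65
AUTOCORR2D_067,autocorr2d:66
AUTOCORR2D_068,autocorr2d:67
AUTOCORR2D_069,autocorr2d:68
AUTOCORR2D_070,autocorr2d:69
AUTOCORR2D_071,autocorr2d:70
AUTOCORR2D_072,autocorr2d:71
AUTOCORR2D_073,autocorr2d:72
AUTOCORR2D_074,autocorr2d:73
AUTOCORR2D_075,autocorr2d:74
AUTOCORR2D_076,autocorr2d:75
AUTOCORR2D_077,autocorr2d:76
AUTOCORR2D_078,autocorr2d:77
AUTOCORR2D_079,autocorr2d:78
AUTOCORR2D_080,autocorr2d:79
AUTOCORR2D_081,autocorr2d:80
AUTOCORR2D_082,autocorr2d:81
AUTOCORR2D_083,autocorr2d:82
AUTOCORR2D_084,autocorr2d:83
AUTOCORR2D_085,autocorr2d:84
AUTOCORR2D_086,autocorr2d:85
AUTOCORR2D_087,autocorr2d:86
AUTOCORR2D_088,autocorr2d:87
AUTOCORR2D_089,autocorr2d:88
AUTOCORR2D_090,autocorr2d:89
AUTOCORR2D_091,autocorr2d:90
AUTOCORR2D_092,autocorr2d:91
AUTOCORR2D_093,autocorr2d:92
AUTOCORR2D_094,autocorr2d:93
AUTOCORR2D_095,autocorr2d:94
AUTOCORR2D_096,autocorr2d:95
AUTOCORR2D_097,autocorr2d:96
AUTOCORR2D_098,autocorr2d:97
AUTOCORR2D_099,autocorr2d:98
AUTOCORR2D_100,autocorr2d:99
AUTOCORR2D_101,autocorr2d:100
AUTOCORR2D_102,autocorr2d:101
AUTOCORR2D_103,autocorr2d:102
AUTOCORR2D_104,autocorr2d:103
AUTOCORR2D_105,autocorr2d:104
AUTOCORR2D_106,autocorr2d:105
AUTOCORR2D_107,autocorr2d:106
AUTOCORR2D_108,autocorr2d:107
AUTOCORR2D_109,autocorr2d:108
AUTOCORR2D_110,autocorr2d:109
AUTOCORR2D_111,autocorr2d:110
AUTOCORR2D_112,autocorr2d:111
AUTOCORR2D_113,autocorr2d:112
AUTOCORR2D_114,autocorr2d:113
AUTOCORR2D_115,autocorr2d:114
AUTOCORR2D_116,autocorr2d:115
AUTOCORR2D_117,autocorr2d:116
AUTOCORR2D_118,autocorr2d:117
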