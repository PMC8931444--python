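wavelength_nm,HbO2,Hb,fat,water
700,0.290,1.794,0.0070,0.0066
710,0.320,1.540,0.0072,0.0073
720,0.356,1.296,0.0078,0.0090
730,0.390,1.102,0.0086,0.0115
740,0.436,1.164,0.0095,0.0149
750,0.518,1.405,0.0104,0.0260
760,0.586,1.674,0.0113,0.0275
770,0.650,1.384,0.0118,0.0250
780,0.710,1.096,0.0120,0.0236
790,0.774,0.952,0.0121,0.0240
800,0.816,0.816,0.0121,0.0224
810,0.864,0.748,0.0122,0.0229
820,0.916,0.698,0.0126,0.0254
830,0.974,0.680,0.0130,0.0290
840,1.022,0.670,0.0138,0.0344
850,1.058,0.691,0.0150,0.0430
860,1.104,0.704,0.0160,0.0460
870,1.142,0.720,0.0172,0.0480
880,1.214,0.742,0.0190,0.0525
890,1.250,0.753,0.0220,0.0585
900,1.274,0.769,0.0280,0.0670
910,1.294,0.792,0.0400,0.0730
920,1.306,0.812,0.0650,0.0840
930,1.312,0.832,0.1100,0.0920
940,1.322,0.860,0.0750,0.1260
950,1.330,0.881,0.0450,0.1680
960,1.334,0.900,0.0350,0.2400
970,1.336,0.921,0.0300,0.4500
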