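# Primary-variable scores (X1..X10) of the 37 county/district health promotion
# policies from the Sichuan pilot areas, as published; PMC = row sum.
policy_id,X1,X2,X3,X4,X5,X6,X7,X8,X9,X10
P1,0.857,0.5,0.5,0.25,0.8,1.0,1.0,0.25,1.0,1.0
P2,0.857,0.25,0.75,0.25,0.8,0.833,0.8,0.25,0.6,1.0
P3,0.714,0.5,0.25,0.25,0.8,0.833,1.0,0.25,0.6,1.0
P4,0.857,0.25,0.25,0.25,0.6,1.0,1.0,0.25,1.0,1.0
P5,1.0,0.75,0.75,0.5,1.0,1.0,1.0,0.25,1.0,1.0
P6,0.429,0.5,0.25,0.5,0.6,1.0,1.0,0.25,1.0,1.0
P7,1.0,1.0,1.0,0.75,1.0,1.0,1.0,0.25,1.0,1.0
P8,0.857,0.25,0.5,0.25,0.8,1.0,1.0,0.25,1.0,1.0
P9,1.0,1.0,0.5,0.5,1.0,1.0,1.0,0.25,1.0,1.0
P10,0.429,1.0,0.75,0.75,0.6,1.0,1.0,0.25,1.0,1.0
P11,0.571,0.25,0.5,0.5,1.0,0.833,0.6,0.25,1.0,1.0
P12,0.714,1.0,1.0,0.75,0.8,1.0,1.0,0.25,1.0,1.0
P13,0.857,0.25,0.25,0.25,0.8,1.0,0.8,0.25,1.0,1.0
P14,0.857,0.25,0.5,0.25,0.8,0.833,0.6,0.25,1.0,1.0
P15,0.714,0.25,0.25,0.5,0.6,0.667,0.6,0.5,0.6,1.0
P16,1.0,0.25,0.25,0.25,0.8,1.0,0.8,0.25,1.0,1.0
P17,0.714,1.0,0.75,0.75,0.6,1.0,1.0,0.25,1.0,1.0
P18,1.0,1.0,0.75,0.5,1.0,1.0,1.0,0.25,1.0,1.0
P19,0.714,0.5,0.0,0.25,0.6,0.833,0.8,0.25,1.0,1.0
P20,0.857,1.0,0.5,0.5,1.0,1.0,1.0,0.25,1.0,1.0
P21,0.857,0.5,0.5,0.5,0.8,1.0,1.0,0.25,1.0,1.0
P22,0.571,0.25,0.75,0.25,0.6,1.0,0.8,0.25,0.8,1.0
P23,0.429,1.0,0.75,0.75,0.6,1.0,1.0,0.25,1.0,1.0
P24,0.429,0.5,0.25,0.5,0.6,1.0,1.0,0.25,1.0,1.0
P25,0.857,0.5,0.75,0.0,0.8,1.0,1.0,0.25,0.8,1.0
P26,0.714,0.5,0.25,0.0,0.8,1.0,0.8,0.25,1.0,1.0
P27,0.857,0.5,0.25,0.25,0.8,1.0,0.8,0.25,1.0,1.0
P28,0.429,0.75,0.75,0.5,0.6,1.0,1.0,0.25,1.0,1.0
P29,0.714,0.75,0.75,0.25,0.8,1.0,1.0,0.25,1.0,1.0
P30,0.571,1.0,0.75,0.5,0.6,1.0,1.0,0.25,1.0,1.0
P31,0.857,0.5,1.0,0.5,1.0,1.0,1.0,0.25,1.0,1.0
P32,0.429,1.0,0.75,0.75,0.6,1.0,1.0,0.25,1.0,1.0
P33,0.571,0.25,0.25,0.0,0.6,0.5,0.4,0.25,0.2,1.0
P34,1.0,0.5,0.75,0.75,1.0,1.0,1.0,0.25,1.0,1.0
P35,0.571,0.5,0.5,0.75,0.6,1.0,1.0,0.25,0.0,1.0
P36,0.714,0.5,0.25,0.0,1.0,1.0,1.0,0.25,1.0,1.0
P37,0.714,0.5,0.75,0.25,0.8,1.0,1.0,0.25,1.0,1.0
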