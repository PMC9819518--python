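city_id,Khon Kaen
year,2019
code,value
VR01,75.20
VR02,6.28
VR03,7.12
VR04,1.92
VR05,13.09
VR06,4.29
VR07,9.69
VR08,61.72
VR09,2.67
VR10,127.39
VR11,50.91
VR12,24.01
VR13,30.52
VR14,4.90
VR15,20.05
VR16,84
VR17,280
VR18,310
VR19,1.50
VR20,381.80
VR21,8.80
VR22,99.62
VR23,25
VR24,77.71
VR25,11.23
VR26,3.03
VR27,3.55
VR28,79.11
VR29,100
VR30,100
VR31,95.08
VR32,1
VR33,17.10
VR34,39.90
VR35,28.85
VR36,0.56
VR37,79.96
VR38,82.87
VR39,2.27
VR40,17.97
VR41,46.37
VR42,2.15
VR43,6.63
VR44,44.99
VR45,2.04
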