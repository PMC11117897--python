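well,compound
A1,blank
A2,PM-M4 carbon source 01
A3,PM-M4 carbon source 02
A4,PM-M4 carbon source 03
A5,PM-M4 carbon source 04
A6,PM-M4 carbon source 05
A7,PM-M4 carbon source 06
A8,PM-M4 carbon source 07
A9,PM-M4 carbon source 08
A10,PM-M4 carbon source 09
A11,PM-M4 carbon source 10
A12,PM-M4 carbon source 11
B1,blank
B2,PM-M4 carbon source 12
B3,PM-M4 carbon source 13
B4,PM-M4 carbon source 14
B5,PM-M4 carbon source 15
B6,PM-M4 carbon source 16
B7,PM-M4 carbon source 17
B8,PM-M4 carbon source 18
B9,PM-M4 carbon source 19
B10,PM-M4 carbon source 20
B11,PM-M4 carbon source 21
B12,PM-M4 carbon source 22
C1,blank
C2,PM-M4 carbon source 23
C3,PM-M4 carbon source 24
C4,PM-M4 carbon source 25
C5,PM-M4 carbon source 26
C6,PM-M4 carbon source 27
C7,PM-M4 carbon source 28
C8,PM-M4 carbon source 29
C9,PM-M4 carbon source 30
C10,PM-M4 carbon source 31
C11,PM-M4 carbon source 32
C12,PM-M4 carbon source 33
D1,blank
D2,PM-M4 carbon source 34
D3,PM-M4 carbon source 35
D4,PM-M4 carbon source 36
D5,PM-M4 carbon source 37
D6,PM-M4 carbon source 38
D7,PM-M4 carbon source 39
D8,PM-M4 carbon source 40
D9,PM-M4 carbon source 41
D10,PM-M4 carbon source 42
D11,PM-M4 carbon source 43
D12,PM-M4 carbon source 44
E1,blank
E2,PM-M4 carbon source 45
E3,PM-M4 carbon source 46
E4,PM-M4 carbon source 47
E5,PM-M4 carbon source 48
E6,PM-M4 carbon source 49
E7,PM-M4 carbon source 50
E8,PM-M4 carbon source 51
E9,PM-M4 carbon source 52
E10,PM-M4 carbon source 53
E11,PM-M4 carbon source 54
E12,PM-M4 carbon source 55
F1,blank
F2,PM-M4 carbon source 56
F3,PM-M4 carbon source 57
F4,PM-M4 carbon source 58
F5,PM-M4 carbon source 59
F6,PM-M4 carbon source 60
F7,PM-M4 carbon source 61
F8,PM-M4 carbon source 62
F9,PM-M4 carbon source 63
F10,PM-M4 carbon source 64
F11,PM-M4 carbon source 65
F12,PM-M4 carbon source 66
G1,blank
G2,PM-M4 carbon source 67
G3,PM-M4 carbon source 68
G4,PM-M4 carbon source 69
G5,PM-M4 carbon source 70
G6,PM-M4 carbon source 71
G7,PM-M4 carbon source 72
G8,PM-M4 carbon source 73
G9,PM-M4 carbon source 74
G10,PM-M4 carbon source 75
G11,PM-M4 carbon source 76
G12,PM-M4 carbon source 77
H1,blank
H2,PM-M4 carbon source 78
H3,PM-M4 carbon source 79
H4,PM-M4 carbon source 80
H5,PM-M4 carbon source 81
H6,PM-M4 carbon source 82
H7,PM-M4 carbon source 83
H8,PM-M4 carbon source 84
H9,PM-M4 carbon source 85
H10,PM-M4 carbon source 86
H11,PM-M4 carbon source 87
H12,PM-M4 carbon source 88
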