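well,compound
A1,db-cAMP 0 uM
A2,db-cAMP 1 uM
A3,db-cAMP 2 uM
A4,db-cAMP 5 uM
A5,db-cAMP 10 uM
A6,db-cAMP 20 uM
A7,db-cAMP 50 uM
A8,db-cAMP 100 uM
A9,db-cAMP 200 uM
A10,db-cAMP 500 uM
A11,db-cAMP 1000 uM
A12,db-cAMP 2000 uM
B1,blank
B2,PM-M6 condition 01
B3,PM-M6 condition 02
B4,PM-M6 condition 03
B5,PM-M6 condition 04
B6,PM-M6 condition 05
B7,PM-M6 condition 06
B8,PM-M6 condition 07
B9,PM-M6 condition 08
B10,PM-M6 condition 09
B11,PM-M6 condition 10
B12,PM-M6 condition 11
C1,blank
C2,PM-M6 condition 12
C3,PM-M6 condition 13
C4,PM-M6 condition 14
C5,PM-M6 condition 15
C6,PM-M6 condition 16
C7,PM-M6 condition 17
C8,PM-M6 condition 18
C9,PM-M6 condition 19
C10,PM-M6 condition 20
C11,PM-M6 condition 21
C12,PM-M6 condition 22
D1,blank
D2,PM-M6 condition 23
D3,PM-M6 condition 24
D4,PM-M6 condition 25
D5,PM-M6 condition 26
D6,PM-M6 condition 27
D7,PM-M6 condition 28
D8,PM-M6 condition 29
D9,PM-M6 condition 30
D10,PM-M6 condition 31
D11,PM-M6 condition 32
D12,PM-M6 condition 33
E1,blank
E2,PM-M6 condition 34
E3,PM-M6 condition 35
E4,PM-M6 condition 36
E5,PM-M6 condition 37
E6,PM-M6 condition 38
E7,PM-M6 condition 39
E8,PM-M6 condition 40
E9,PM-M6 condition 41
E10,PM-M6 condition 42
E11,PM-M6 condition 43
E12,PM-M6 condition 44
F1,blank
F2,PM-M6 condition 45
F3,PM-M6 condition 46
F4,PM-M6 condition 47
F5,PM-M6 condition 48
F6,PM-M6 condition 49
F7,PM-M6 condition 50
F8,PM-M6 condition 51
F9,PM-M6 condition 52
F10,PM-M6 condition 53
F11,PM-M6 condition 54
F12,PM-M6 condition 55
G1,blank
G2,PM-M6 condition 56
G3,PM-M6 condition 57
G4,PM-M6 condition 58
G5,PM-M6 condition 59
G6,PM-M6 condition 60
G7,PM-M6 condition 61
G8,PM-M6 condition 62
G9,PM-M6 condition 63
G10,PM-M6 condition 64
G11,PM-M6 condition 65
G12,PM-M6 condition 66
H1,blank
H2,PM-M6 condition 67
H3,PM-M6 condition 68
H4,PM-M6 condition 69
H5,PM-M6 condition 70
H6,PM-M6 condition 71
H7,PM-M6 condition 72
H8,PM-M6 condition 73
H9,PM-M6 condition 74
H10,PM-M6 condition 75
H11,PM-M6 condition 76
H12,PM-M6 condition 77
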