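well,compound
A1,blank
A2,D-glucose-6-phosphate
A3,D-glucose-1-phosphate
A4,D-glucose
A5,D-mannose
A6,D-fructose-6-phosphate
A7,D-fructose
A8,D-galactose
A9,lactic acid
A10,alpha-ketoglutaric acid
A11,succinamic acid
A12,mono-methyl succinate
B1,blank
B2,L-glutamine
B3,adenosine
B4,inosine
B5,PM-M1 carbon source 01
B6,PM-M1 carbon source 02
B7,PM-M1 carbon source 03
B8,PM-M1 carbon source 04
B9,PM-M1 carbon source 05
B10,PM-M1 carbon source 06
B11,PM-M1 carbon source 07
B12,PM-M1 carbon source 08
C1,blank
C2,PM-M1 carbon source 09
C3,PM-M1 carbon source 10
C4,PM-M1 carbon source 11
C5,PM-M1 carbon source 12
C6,PM-M1 carbon source 13
C7,PM-M1 carbon source 14
C8,PM-M1 carbon source 15
C9,PM-M1 carbon source 16
C10,PM-M1 carbon source 17
C11,PM-M1 carbon source 18
C12,PM-M1 carbon source 19
D1,blank
D2,PM-M1 carbon source 20
D3,PM-M1 carbon source 21
D4,PM-M1 carbon source 22
D5,PM-M1 carbon source 23
D6,PM-M1 carbon source 24
D7,PM-M1 carbon source 25
D8,PM-M1 carbon source 26
D9,PM-M1 carbon source 27
D10,PM-M1 carbon source 28
D11,PM-M1 carbon source 29
D12,PM-M1 carbon source 30
E1,blank
E2,PM-M1 carbon source 31
E3,PM-M1 carbon source 32
E4,PM-M1 carbon source 33
E5,PM-M1 carbon source 34
E6,PM-M1 carbon source 35
E7,PM-M1 carbon source 36
E8,PM-M1 carbon source 37
E9,PM-M1 carbon source 38
E10,PM-M1 carbon source 39
E11,PM-M1 carbon source 40
E12,PM-M1 carbon source 41
F1,blank
F2,PM-M1 carbon source 42
F3,PM-M1 carbon source 43
F4,PM-M1 carbon source 44
F5,PM-M1 carbon source 45
F6,PM-M1 carbon source 46
F7,PM-M1 carbon source 47
F8,PM-M1 carbon source 48
F9,PM-M1 carbon source 49
F10,PM-M1 carbon source 50
F11,PM-M1 carbon source 51
F12,PM-M1 carbon source 52
G1,blank
G2,PM-M1 carbon source 53
G3,PM-M1 carbon source 54
G4,PM-M1 carbon source 55
G5,PM-M1 carbon source 56
G6,PM-M1 carbon source 57
G7,PM-M1 carbon source 58
G8,PM-M1 carbon source 59
G9,PM-M1 carbon source 60
G10,PM-M1 carbon source 61
G11,PM-M1 carbon source 62
G12,PM-M1 carbon source 63
H1,blank
H2,PM-M1 carbon source 64
H3,PM-M1 carbon source 65
H4,PM-M1 carbon source 66
H5,PM-M1 carbon source 67
H6,PM-M1 carbon source 68
H7,PM-M1 carbon source 69
H8,PM-M1 carbon source 70
H9,PM-M1 carbon source 71
H10,PM-M1 carbon source 72
H11,PM-M1 carbon source 73
H12,PM-M1 carbon source 74
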