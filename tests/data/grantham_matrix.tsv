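aa1	aa2	distance
A	C	195
A	D	126
A	E	107
A	F	113
A	G	60
A	H	86
A	I	94
A	K	106
A	L	96
A	M	85
A	N	111
A	P	27
A	Q	91
A	R	111
A	S	99
A	T	58
A	V	65
A	W	148
A	Y	112
C	D	154
C	E	170
C	F	205
C	G	158
C	H	174
C	I	198
C	K	202
C	L	198
C	M	196
C	N	139
C	P	169
C	Q	154
C	R	180
C	S	112
C	T	149
C	V	191
C	W	215
C	Y	194
D	E	45
D	F	177
D	G	94
D	H	81
D	I	168
D	K	102
D	L	172
D	M	160
D	N	23
D	P	108
D	Q	61
D	R	96
D	S	66
D	T	85
D	V	152
D	W	191
D	Y	160
E	F	140
E	G	98
E	H	41
E	I	134
E	K	57
E	L	139
E	M	126
E	N	41
E	P	94
E	Q	29
E	R	54
E	S	80
E	T	66
E	V	121
E	W	152
E	Y	123
F	G	153
F	H	100
F	I	21
F	K	102
F	L	22
F	M	29
F	N	158
F	P	114
F	Q	116
F	R	97
F	S	155
F	T	103
F	V	50
F	W	40
F	Y	22
G	H	98
G	I	136
G	K	127
G	L	138
G	M	127
G	N	79
G	P	42
G	Q	87
G	R	125
G	S	55
G	T	59
G	V	109
G	W	184
G	Y	147
H	I	94
H	K	32
H	L	99
H	M	86
H	N	68
H	P	76
H	Q	24
H	R	29
H	S	89
H	T	47
H	V	84
H	W	115
H	Y	83
I	K	102
I	L	5
I	M	10
I	N	149
I	P	96
I	Q	109
I	R	98
I	S	142
I	T	89
I	V	30
I	W	61
I	Y	33
K	L	106
K	M	95
K	N	94
K	P	103
K	Q	53
K	R	26
K	S	121
K	T	78
K	V	97
K	W	110
K	Y	85
L	M	14
L	N	153
L	P	98
L	Q	113
L	R	102
L	S	144
L	T	92
L	V	32
L	W	61
L	Y	36
M	N	141
M	P	87
M	Q	101
M	R	92
M	S	135
M	T	81
M	V	22
M	W	67
M	Y	35
N	P	90
N	Q	46
N	R	85
N	S	46
N	T	65
N	V	133
N	W	174
N	Y	142
P	Q	75
P	R	103
P	S	73
P	T	38
P	V	68
P	W	147
P	Y	110
Q	R	43
Q	S	68
Q	T	41
Q	V	96
Q	W	130
Q	Y	99
R	S	109
R	T	71
R	V	96
R	W	101
R	Y	77
S	T	58
S	V	123
S	W	177
S	Y	143
T	V	70
T	W	128
T	Y	92
V	W	88
V	Y	55
W	Y	37
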