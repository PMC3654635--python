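sample_id	marker	allele1	allele2
FATHER	D6S1571	160	162
FATHER	D6S1260	130	132
FATHER	D6S1624	200	202
FATHER	MOG-CA	205	207
FATHER	MOG-TAAA	125	127
FATHER	D6S265	110	112
FATHER	HLAC-CA	155	157
FATHER	MIB	155	157
FATHER	D6S273	135	137
FATHER	D6S1618	130	132
FATHER	DRA-CA	120	122
FATHER	D6S2443	150	152
FATHER	DQCAR	150	152
FATHER	TAP1-CA	195	197
FATHER	RING3-CA	125	127
FATHER	D6S1560	225	227
FATHER	D6S1583	150	152
FATHER	D6S1611	225	227
FATHER	D6S1610	100	102
FATHER	D6S1552	160	162
FATHER	D11S1338	250	252
FATHER	D11S4891	75	77
FATHER	D11S1760	75	77
FATHER	D11S1871	160	162
FATHER	D11S2351	150	152
FATHER	D11S4181	200	202
MOTHER	D6S1571	164	166
MOTHER	D6S1260	134	136
MOTHER	D6S1624	204	206
MOTHER	MOG-CA	209	211
MOTHER	MOG-TAAA	129	131
MOTHER	D6S265	114	116
MOTHER	HLAC-CA	159	161
MOTHER	MIB	159	161
MOTHER	D6S273	139	141
MOTHER	D6S1618	134	136
MOTHER	DRA-CA	124	126
MOTHER	D6S2443	154	156
MOTHER	DQCAR	154	156
MOTHER	TAP1-CA	199	201
MOTHER	RING3-CA	129	131
MOTHER	D6S1560	229	231
MOTHER	D6S1583	154	156
MOTHER	D6S1611	229	231
MOTHER	D6S1610	104	106
MOTHER	D6S1552	164	166
MOTHER	D11S1338	254	256
MOTHER	D11S4891	79	81
MOTHER	D11S1760	79	81
MOTHER	D11S1871	164	166
MOTHER	D11S2351	154	156
MOTHER	D11S4181	204	206
CHILD	D6S1571	160	164
CHILD	D6S1260	130	134
CHILD	D6S1624	200	204
CHILD	MOG-CA	205	209
CHILD	MOG-TAAA	125	129
CHILD	D6S265	110	114
CHILD	HLAC-CA	155	159
CHILD	MIB	155	159
CHILD	D6S273	135	139
CHILD	D6S1618	130	134
CHILD	DRA-CA	120	124
CHILD	D6S2443	150	154
CHILD	DQCAR	150	154
CHILD	TAP1-CA	195	199
CHILD	RING3-CA	125	129
CHILD	D6S1560	225	229
CHILD	D6S1583	150	154
CHILD	D6S1611	225	229
CHILD	D6S1610	100	104
CHILD	D6S1552	160	164
CHILD	D11S1338	250	254
CHILD	D11S4891	75	79
CHILD	D11S1760	75	79
CHILD	D11S1871	160	164
CHILD	D11S2351	150	154
CHILD	D11S4181	200	204
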