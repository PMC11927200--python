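accession	residue	value
FASG760101	A	89.09
FASG760101	R	174.2
FASG760101	N	132.12
FASG760101	D	133.1
FASG760101	C	121.15
FASG760101	Q	146.15
FASG760101	E	147.13
FASG760101	G	75.07
FASG760101	H	155.16
FASG760101	I	131.17
FASG760101	L	131.17
FASG760101	K	146.19
FASG760101	M	149.21
FASG760101	F	165.19
FASG760101	P	115.13
FASG760101	S	105.09
FASG760101	T	119.12
FASG760101	W	204.24
FASG760101	Y	181.19
FASG760101	V	117.15
FASG760102	A	297
FASG760102	R	238
FASG760102	N	236
FASG760102	D	270
FASG760102	C	178
FASG760102	Q	185
FASG760102	E	249
FASG760102	G	290
FASG760102	H	277
FASG760102	I	284
FASG760102	L	337
FASG760102	K	224
FASG760102	M	283
FASG760102	F	284
FASG760102	P	222
FASG760102	S	228
FASG760102	T	253
FASG760102	W	282
FASG760102	Y	344
FASG760102	V	293
GOLD730102	A	88.3
GOLD730102	R	181.2
GOLD730102	N	125.1
GOLD730102	D	110.8
GOLD730102	C	112.4
GOLD730102	Q	148.7
GOLD730102	E	140.5
GOLD730102	G	60
GOLD730102	H	152.6
GOLD730102	I	168.5
GOLD730102	L	168.5
GOLD730102	K	175.6
GOLD730102	M	162.2
GOLD730102	F	189
GOLD730102	P	122.2
GOLD730102	S	88.7
GOLD730102	T	118.2
GOLD730102	W	227
GOLD730102	Y	193
GOLD730102	V	141.4
WOLR790101	A	1.12
WOLR790101	R	-2.55
WOLR790101	N	-0.83
WOLR790101	D	-0.83
WOLR790101	C	0.59
WOLR790101	Q	-0.78
WOLR790101	E	-0.92
WOLR790101	G	1.2
WOLR790101	H	-0.93
WOLR790101	I	1.16
WOLR790101	L	1.18
WOLR790101	K	-0.8
WOLR790101	M	0.55
WOLR790101	F	0.67
WOLR790101	P	0.54
WOLR790101	S	-0.05
WOLR790101	T	-0.02
WOLR790101	W	-0.19
WOLR790101	Y	-0.23
WOLR790101	V	1.13
BHAR880101	A	0.357
BHAR880101	R	0.529
BHAR880101	N	0.463
BHAR880101	D	0.511
BHAR880101	C	0.346
BHAR880101	Q	0.493
BHAR880101	E	0.497
BHAR880101	G	0.544
BHAR880101	H	0.323
BHAR880101	I	0.462
BHAR880101	L	0.365
BHAR880101	K	0.466
BHAR880101	M	0.295
BHAR880101	F	0.314
BHAR880101	P	0.509
BHAR880101	S	0.507
BHAR880101	T	0.444
BHAR880101	W	0.305
BHAR880101	Y	0.42
BHAR880101	V	0.386
BULH740101	A	-0.2
BULH740101	R	-0.12
BULH740101	N	0.08
BULH740101	D	-0.2
BULH740101	C	-0.45
BULH740101	Q	0.16
BULH740101	E	-0.3
BULH740101	G	0
BULH740101	H	-0.12
BULH740101	I	-2.26
BULH740101	L	-2.46
BULH740101	K	-0.35
BULH740101	M	-1.47
BULH740101	F	-2.33
BULH740101	P	-0.98
BULH740101	S	-0.39
BULH740101	T	-0.52
BULH740101	W	-2.01
BULH740101	Y	-2.24
BULH740101	V	-1.56
FAUJ880108	A	-0.01
FAUJ880108	R	0.04
FAUJ880108	N	0.06
FAUJ880108	D	0.15
FAUJ880108	C	0.12
FAUJ880108	Q	0.05
FAUJ880108	E	0.07
FAUJ880108	G	0
FAUJ880108	H	0.08
FAUJ880108	I	-0.01
FAUJ880108	L	-0.01
FAUJ880108	K	0
FAUJ880108	M	0.04
FAUJ880108	F	0.03
FAUJ880108	P	0
FAUJ880108	S	0.11
FAUJ880108	T	0.04
FAUJ880108	W	0
FAUJ880108	Y	0.03
FAUJ880108	V	0.01
ZIMJ680103	A	0
ZIMJ680103	R	52
ZIMJ680103	N	3.38
ZIMJ680103	D	49.7
ZIMJ680103	C	1.48
ZIMJ680103	Q	3.53
ZIMJ680103	E	49.9
ZIMJ680103	G	0
ZIMJ680103	H	51.6
ZIMJ680103	I	0.13
ZIMJ680103	L	0.13
ZIMJ680103	K	49.5
ZIMJ680103	M	1.43
ZIMJ680103	F	0.35
ZIMJ680103	P	1.58
ZIMJ680103	S	1.67
ZIMJ680103	T	1.66
ZIMJ680103	W	2.1
ZIMJ680103	Y	1.61
ZIMJ680103	V	0.13
ZIMJ680104	A	6
ZIMJ680104	R	10.76
ZIMJ680104	N	5.41
ZIMJ680104	D	2.77
ZIMJ680104	C	5.05
ZIMJ680104	Q	5.65
ZIMJ680104	E	3.22
ZIMJ680104	G	5.97
ZIMJ680104	H	7.59
ZIMJ680104	I	6.02
ZIMJ680104	L	5.98
ZIMJ680104	K	9.74
ZIMJ680104	M	5.74
ZIMJ680104	F	5.48
ZIMJ680104	P	6.3
ZIMJ680104	S	5.68
ZIMJ680104	T	5.66
ZIMJ680104	W	5.89
ZIMJ680104	Y	5.66
ZIMJ680104	V	5.96
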