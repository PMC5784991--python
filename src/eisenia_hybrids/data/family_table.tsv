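family_id	parent1	parent2	generation	offspring
1a	aAA25	fFF26	F1	[aAF46; aAA45]; [aAA62; fFF61]; aAF57/90; aAA58; aAA59; aAA63; aAA91; aAA92
1b	aAF46Mp	aAA45	F2	aAA109; aAA110; aAF95; aAF96/103
1c	aAA62	fFF61	F1	[aAF76/137; aAA83/138]; [aAF77/142; aAA87]; [aAF98/152; aAA97/153]; aAA170; aAF171; aAF172; aAA173
1d	aAF76/137	aAA83/138	F2	aAF84/139; aAA85/140; aAF86/141; aAA96; aAA141; aAA174; aAA175
1e	aAF77/142	aAA87	F2	aAA88; aAA89
1f	aAF98/152	aAA97/153	F2	aAF154; aAA155; aAA156; aAA157; aAA176
2a	aAA37	fFF38	F1	aAA65; fFF64/192; [aAF78; fFF75]
2b	aAF78	fFF75	F2	[aAF79; aAF82]
2c	aAF79	aAF82	F3	---
3a	aAA31	fFF32	F1	aAA39; [aAA71; fFF72]; [aAF99; aAF100]; [aAF101; aAF102]
3b	aAA71	fFF72	F1	[aAF93; aAF94]
3c	aAF99	aAF100	F2	---
3d	aAF101	aAF102	F2	---
3e	aAF93	aAF94	F2	---
4a	aAA33	fFF34	F1	aAF40; [fFF67; aAF68]; aAF115; fFF116
4b	aAF68	fFF67	F2	fFF148; fFA149/194; fFF150; fFF151; fFA162; aAF167
4c	fFA149/194	aAF86/141	F3	---
4d	fFA162	aAF172	F3	---
5a	aAA29	fFF30	F1	[aAF48; fFF47]
5b	aAF48	fFF47	F2	[fFA108/196; fFF107/197]; [fFA143/159/191; fFF158]; fFF144; fFF145; fFF160; fFF161; fFF178; fFF179; fFF180; fFF181
5c	fFA108/196	fFF107/197	F3	---
5d	fFA143/159/191	fFF158	F3	---
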