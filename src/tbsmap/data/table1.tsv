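site	1CH	1BB	1IP	12DBE	12DBP	BCH	CCP
1	73.9	39.7	28.3	48.0	47.1	82.9	54.8
2	21.3	-	-	-	-	-	-
3	23.0	-	26.4	54.4	62.4	68.9	25.4
4	59.9	17.2	9.3	26.2	20.1	45.8	-
5	96.6	-	-	-	-	32.8	38.2
6	-	-	-	-	-	16.5	-
7	32.0	-	-	-	-	-	-
8	-	-	-	-	-	-	20.5
9	-	-	-	-	-	-	15.7
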