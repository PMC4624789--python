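haplogroup	Huelva	Granada	Asni	Bouhria	Figuig
n	280	470	53	70	94
U6	21	7	6	1	3
U6a	18	5	5	1	3
U6bd	2	2	1	-	-
U6c	1	-	-	-	-
M1	1	3	2	3	2
L	11	7	12	9	42
L0	-	1	-	-	4
L1b	4	-	4	5	6
L2a	2	1	1	2	3
L2b	3	-	2	-	-
L2d	-	-	-	-	1
L3b	-	-	-	-	8
L3d	-	2	-	-	-
L3e	-	-	4	2	20
L3f1b	2	-	-	-	-
L3h1b	-	2	-	-	-
L3x	-	1	-	-	-
L5	-	-	1	-	-
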