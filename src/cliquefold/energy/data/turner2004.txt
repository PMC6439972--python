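# cliquefold nearest-neighbor parameters
# Turner 2004 free-energy release, 37 degrees C, kcal/mol
# pair columns/rows ordered: CG GC GU UG AU UA

[stack]
CG CG -2.40
CG GC -3.30
CG GU -2.10
CG UG -1.40
CG AU -2.10
CG UA -2.10
GC CG -3.30
GC GC -3.40
GC GU -2.50
GC UG -1.50
GC AU -2.20
GC UA -2.40
GU CG -2.10
GU GC -2.50
GU GU 1.30
GU UG -0.50
GU AU -1.40
GU UA -1.30
UG CG -1.40
UG GC -1.50
UG GU -0.50
UG UG 0.30
UG AU -0.60
UG UA -1.00
AU CG -2.10
AU GC -2.20
AU GU -1.40
AU UG -0.60
AU AU -1.10
AU UA -0.90
UA CG -2.10
UA GC -2.40
UA GU -1.30
UA UG -1.00
UA AU -0.90
UA UA -1.30

[hairpin_length]
3 5.40
4 5.60
5 5.70
6 5.40
7 6.00
8 5.50
9 6.40
10 6.50
11 6.60
12 6.70
13 6.80
14 6.90
15 6.90
16 7.00
17 7.10
18 7.10
19 7.20
20 7.20
21 7.30
22 7.30
23 7.40
24 7.40
25 7.50
26 7.50
27 7.50
28 7.60
29 7.60
30 7.70

[bulge_length]
1 3.80
2 2.80
3 3.20
4 3.60
5 4.00
6 4.40
7 4.60
8 4.70
9 4.80
10 4.90
11 5.00
12 5.10
13 5.20
14 5.30
15 5.40
16 5.40
17 5.50
18 5.50
19 5.60
20 5.70
21 5.70
22 5.80
23 5.80
24 5.80
25 5.90
26 5.90
27 6.00
28 6.00
29 6.00
30 6.10

[internal_length]
2 1.00
3 1.00
4 1.10
5 2.00
6 2.00
7 2.10
8 2.30
9 2.40
10 2.50
11 2.60
12 2.70
13 2.80
14 2.90
15 2.90
16 3.00
17 3.10
18 3.10
19 3.20
20 3.30
21 3.30
22 3.40
23 3.40
24 3.50
25 3.50
26 3.50
27 3.60
28 3.60
29 3.70
30 3.70

[mismatch_hairpin]
CG A A -1.50
CG A C -1.50
CG A G -1.40
CG A U -1.50
CG C A -1.00
CG C C -1.10
CG C G -1.00
CG C U -0.80
CG G A -2.30
CG G C -1.50
CG G G -2.40
CG G U -1.50
CG U A -1.00
CG U C -1.40
CG U G -1.00
CG U U -2.10
GC A A -1.10
GC A C -1.50
GC A G -1.30
GC A U -1.50
GC C A -1.10
GC C C -0.70
GC C G -1.10
GC C U -0.50
GC G A -2.50
GC G C -1.50
GC G G -2.20
GC G U -1.50
GC U A -1.10
GC U C -1.00
GC U G -1.10
GC U U -1.60
GU A A 0.20
GU A C -0.50
GU A G -0.30
GU A U -0.50
GU C A -0.10
GU C C -0.20
GU C G -0.10
GU C U -0.20
GU G A -1.00
GU G C -0.50
GU G G -1.10
GU G U -0.50
GU U A -0.10
GU U C -0.30
GU U G -0.10
GU U U -1.00
UG A A -0.50
UG A C -0.30
UG A G -0.60
UG A U -0.30
UG C A -0.20
UG C C -0.10
UG C G -0.20
UG C U 0.00
UG G A -0.90
UG G C -0.30
UG G G -1.10
UG G U -0.30
UG U A -0.20
UG U C -0.10
UG U G -0.20
UG U U -0.90
AU A A -0.30
AU A C -0.50
AU A G -0.30
AU A U -0.50
AU C A -0.10
AU C C -0.20
AU C G -0.10
AU C U -0.20
AU G A -1.20
AU G C -0.50
AU G G -1.10
AU G U -0.50
AU U A -0.10
AU U C -0.30
AU U G -0.10
AU U U -1.20
UA A A -0.50
UA A C -0.30
UA A G -0.50
UA A U -0.30
UA C A -0.20
UA C C -0.10
UA C G -0.20
UA C U 0.00
UA G A -1.50
UA G C -0.30
UA G G -1.50
UA G U -0.30
UA U A -0.20
UA U C -0.10
UA U G -0.20
UA U U -0.90

[mismatch_internal]
CG A A 0.00
CG A C 0.00
CG A G -0.80
CG A U 0.00
CG C A 0.00
CG C C 0.00
CG C G 0.00
CG C U 0.00
CG G A -1.00
CG G C 0.00
CG G G -1.00
CG G U 0.00
CG U A 0.00
CG U C 0.00
CG U G 0.00
CG U U -0.60
GC A A 0.00
GC A C 0.00
GC A G -0.80
GC A U 0.00
GC C A 0.00
GC C C 0.00
GC C G 0.00
GC C U 0.00
GC G A -1.00
GC G C 0.00
GC G G -1.00
GC G U 0.00
GC U A 0.00
GC U C 0.00
GC U G 0.00
GC U U -0.60
GU A A 0.70
GU A C 0.70
GU A G -0.10
GU A U 0.70
GU C A 0.70
GU C C 0.70
GU C G 0.70
GU C U 0.70
GU G A -0.30
GU G C 0.70
GU G G -0.30
GU G U 0.70
GU U A 0.70
GU U C 0.70
GU U G 0.70
GU U U 0.10
UG A A 0.70
UG A C 0.70
UG A G -0.10
UG A U 0.70
UG C A 0.70
UG C C 0.70
UG C G 0.70
UG C U 0.70
UG G A -0.30
UG G C 0.70
UG G G -0.30
UG G U 0.70
UG U A 0.70
UG U C 0.70
UG U G 0.70
UG U U 0.10
AU A A 0.70
AU A C 0.70
AU A G -0.10
AU A U 0.70
AU C A 0.70
AU C C 0.70
AU C G 0.70
AU C U 0.70
AU G A -0.30
AU G C 0.70
AU G G -0.30
AU G U 0.70
AU U A 0.70
AU U C 0.70
AU U G 0.70
AU U U 0.10
UA A A 0.70
UA A C 0.70
UA A G -0.10
UA A U 0.70
UA C A 0.70
UA C C 0.70
UA C G 0.70
UA C U 0.70
UA G A -0.30
UA G C 0.70
UA G G -0.30
UA G U 0.70
UA U A 0.70
UA U C 0.70
UA U G 0.70
UA U U 0.10

[multiloop]
unpaired 0.00
closing 9.30
branch -0.90

[ninio]
per_asym 0.60
max_asym 3.00

[misc]
duplex_init 4.10
terminal_au 0.50
lxc 1.07856

[special_hairpins]
CAACG 6.80
GUUAC 6.90
CAACGG 5.50
CCAAGG 3.30
CCACGG 3.70
CCCAGG 3.40
CCGAGG 3.50
CCGCGG 3.60
CCUAGG 3.70
CCUCGG 2.50
CUAAGG 3.60
CUACGG 2.80
CUCAGG 3.70
CUCCGG 2.70
CUGCGG 2.80
CUUAGG 3.50
CUUCGG 3.70
CUUUGG 3.70
ACAGUACU 2.80
ACAGUGAU 3.60
ACAGUGCU 2.90
ACAGUGUU 1.80

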