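# REBA table C (score_a 1..12 x score_b 1..12 -> score 1..12),
# transcribed from the published Rapid Entire Body Assessment method
# (Hignett & McAtamney 2000, Applied Ergonomics 31:201-205).
# Wide layout: row = score_a, columns b1..b12 = score_b.
score_a,b1,b2,b3,b4,b5,b6,b7,b8,b9,b10,b11,b12
1,1,1,1,2,3,3,4,5,6,7,7,7
2,1,2,2,3,4,4,5,6,6,7,7,8
3,2,3,3,3,4,5,6,7,7,8,8,8
4,3,4,4,4,5,6,7,8,8,9,9,9
5,4,4,4,5,6,7,8,8,9,9,9,9
6,6,6,6,7,8,8,9,9,10,10,10,10
7,7,7,7,8,9,9,9,10,10,11,11,11
8,8,8,8,9,10,10,10,10,10,11,11,11
9,9,9,9,10,10,10,11,11,11,12,12,12
10,10,10,10,11,11,11,11,12,12,12,12,12
11,11,11,11,11,12,12,12,12,12,12,12,12
12,12,12,12,12,12,12,12,12,12,12,12,12
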