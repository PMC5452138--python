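# Simplified nearest-neighbor free-energy parameters (37 C, kcal/mol).
# Turner-style stacking values for the six canonical pairs (incl. GU wobble),
# tabulated loop initiation penalties for sizes up to 30, logarithmic
# extrapolation beyond (coefficient = 1.75*R*T).

[pairs]
AU CG GC GU UA UG

[stack]
# rows = closing pair (i,j); columns = inner pair (i+1,j-1)
          AU     CG     GC     GU     UA     UG
AU      -0.9   -2.2   -2.1   -0.6   -1.1   -1.4
CG      -2.1   -3.3   -2.4   -1.4   -2.1   -2.1
GC      -2.4   -3.4   -3.3   -1.5   -2.2   -2.5
GU      -1.3   -2.5   -2.1   -0.5   -1.4    1.3
UA      -1.3   -2.4   -2.1   -1.0   -0.9   -1.3
UG      -1.0   -1.5   -1.4    0.3   -0.6   -0.5

[hairpin]
3   5.40
4   5.60
5   5.70
6   5.40
7   6.00
8   5.50
9   6.40
10  6.51
11  6.62
12  6.71
13  6.80
14  6.88
15  6.95
16  7.02
17  7.09
18  7.15
19  7.21
20  7.26
21  7.31
22  7.36
23  7.41
24  7.46
25  7.50
26  7.54
27  7.59
28  7.62
29  7.66
30  7.70

[bulge]
1   3.80
2   2.80
3   3.20
4   3.60
5   4.00
6   4.40
7   4.60
8   4.70
9   4.80
10  4.91
11  5.02
12  5.11
13  5.20
14  5.28
15  5.35
16  5.42
17  5.49
18  5.55
19  5.61
20  5.66
21  5.71
22  5.76
23  5.81
24  5.86
25  5.90
26  5.94
27  5.99
28  6.02
29  6.06
30  6.10

[internal]
2   1.50
3   1.60
4   1.70
5   1.80
6   2.00
7   2.20
8   2.30
9   2.40
10  2.51
11  2.62
12  2.71
13  2.80
14  2.88
15  2.95
16  3.02
17  3.09
18  3.15
19  3.21
20  3.26
21  3.31
22  3.36
23  3.41
24  3.46
25  3.50
26  3.54
27  3.59
28  3.62
29  3.66
30  3.70

[multiloop]
a 3.4
b 0.4
c 0.0

[extrapolation]
coef 1.079
max_tabulated 30

[rules]
min_hairpin_loop 3
max_internal_loop 30
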