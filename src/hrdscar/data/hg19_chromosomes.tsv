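chrom	length	cen_start	cen_end
1	249200000	121500000	124500000
2	243100000	92300000	95300000
3	198000000	90500000	93500000
4	191100000	49700000	52700000
5	180900000	46400000	49400000
6	171100000	58800000	61800000
7	159100000	58100000	61100000
8	146300000	43800000	46800000
9	141200000	47400000	50400000
10	135500000	39300000	42300000
11	135000000	51600000	54600000
12	133800000	34900000	37900000
13	115100000	16000000	19000000
14	107300000	16000000	19000000
15	102500000	17000000	20000000
16	90300000	35300000	38300000
17	81100000	22300000	25300000
18	78000000	15500000	18500000
19	59100000	24700000	27700000
20	63000000	26400000	29400000
21	48100000	11300000	14300000
22	51300000	13000000	16000000
X	155200000	58600000	61600000
Y	59300000	10100000	13100000
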