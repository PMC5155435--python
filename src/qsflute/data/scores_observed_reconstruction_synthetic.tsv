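density_cells_per_ml	height_mm	time_h	level
1000.0	2.0	48.0	0
1000.0	2.0	72.0	0
1000.0	2.0	96.0	0
1000.0	4.0	48.0	0
1000.0	4.0	72.0	0
1000.0	4.0	96.0	0
1000.0	6.0	48.0	0
1000.0	6.0	72.0	0
1000.0	6.0	96.0	0
1000.0	8.0	48.0	0
1000.0	8.0	72.0	0
1000.0	8.0	96.0	0
1000.0	10.0	48.0	0
1000.0	10.0	72.0	0
1000.0	10.0	96.0	0
1000.0	12.0	48.0	0
1000.0	12.0	72.0	0
1000.0	12.0	96.0	0
1000.0	14.0	48.0	0
1000.0	14.0	72.0	0
1000.0	14.0	96.0	0
1000.0	16.0	48.0	0
1000.0	16.0	72.0	0
1000.0	16.0	96.0	1
1000.0	18.0	48.0	0
1000.0	18.0	72.0	0
1000.0	18.0	96.0	1
1000.0	20.0	48.0	0
1000.0	20.0	72.0	0
1000.0	20.0	96.0	1
10000.0	2.0	48.0	0
10000.0	2.0	72.0	0
10000.0	2.0	96.0	0
10000.0	4.0	48.0	0
10000.0	4.0	72.0	0
10000.0	4.0	96.0	0
10000.0	6.0	48.0	0
10000.0	6.0	72.0	0
10000.0	6.0	96.0	0
10000.0	8.0	48.0	0
10000.0	8.0	72.0	0
10000.0	8.0	96.0	0
10000.0	10.0	48.0	1
10000.0	10.0	72.0	1
10000.0	10.0	96.0	1
10000.0	12.0	48.0	1
10000.0	12.0	72.0	1
10000.0	12.0	96.0	1
10000.0	14.0	48.0	1
10000.0	14.0	72.0	2
10000.0	14.0	96.0	2
10000.0	16.0	48.0	1
10000.0	16.0	72.0	2
10000.0	16.0	96.0	3
10000.0	18.0	48.0	1
10000.0	18.0	72.0	2
10000.0	18.0	96.0	3
10000.0	20.0	48.0	1
10000.0	20.0	72.0	2
10000.0	20.0	96.0	3
100000.0	2.0	48.0	0
100000.0	2.0	72.0	0
100000.0	2.0	96.0	0
100000.0	4.0	48.0	0
100000.0	4.0	72.0	0
100000.0	4.0	96.0	0
100000.0	6.0	48.0	0
100000.0	6.0	72.0	0
100000.0	6.0	96.0	0
100000.0	8.0	48.0	1
100000.0	8.0	72.0	1
100000.0	8.0	96.0	0
100000.0	10.0	48.0	1
100000.0	10.0	72.0	1
100000.0	10.0	96.0	1
100000.0	12.0	48.0	2
100000.0	12.0	72.0	2
100000.0	12.0	96.0	2
100000.0	14.0	48.0	2
100000.0	14.0	72.0	3
100000.0	14.0	96.0	3
100000.0	16.0	48.0	2
100000.0	16.0	72.0	3
100000.0	16.0	96.0	3
100000.0	18.0	48.0	2
100000.0	18.0	72.0	3
100000.0	18.0	96.0	3
100000.0	20.0	48.0	2
100000.0	20.0	72.0	3
100000.0	20.0	96.0	3
1000000.0	2.0	48.0	0
1000000.0	2.0	72.0	0
1000000.0	2.0	96.0	0
1000000.0	4.0	48.0	0
1000000.0	4.0	72.0	0
1000000.0	4.0	96.0	0
1000000.0	6.0	48.0	0
1000000.0	6.0	72.0	0
1000000.0	6.0	96.0	0
1000000.0	8.0	48.0	1
1000000.0	8.0	72.0	1
1000000.0	8.0	96.0	0
1000000.0	10.0	48.0	1
1000000.0	10.0	72.0	1
1000000.0	10.0	96.0	1
1000000.0	12.0	48.0	2
1000000.0	12.0	72.0	2
1000000.0	12.0	96.0	2
1000000.0	14.0	48.0	2
1000000.0	14.0	72.0	3
1000000.0	14.0	96.0	3
1000000.0	16.0	48.0	2
1000000.0	16.0	72.0	3
1000000.0	16.0	96.0	3
1000000.0	18.0	48.0	3
1000000.0	18.0	72.0	3
1000000.0	18.0	96.0	3
1000000.0	20.0	48.0	3
1000000.0	20.0	72.0	3
1000000.0	20.0	96.0	3
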