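row,col,has_monitor,n_monitors,has_health_data,jurisdiction
1,1,0,0,1,
1,2,0,0,1,
1,3,0,0,0,
1,4,0,0,0,
1,5,0,0,0,
1,6,0,0,0,
1,7,0,0,0,
1,8,0,0,0,
1,9,0,0,0,
2,1,0,0,1,
2,2,0,0,1,
2,3,0,0,0,
2,4,0,0,0,
2,5,0,0,0,
2,6,1,1,1,PG
2,7,0,0,0,
2,8,0,0,0,
2,9,0,0,0,
3,1,0,0,1,
3,2,0,0,1,
3,3,0,0,1,
3,4,0,0,0,
3,5,1,1,1,PG
3,6,0,0,0,
3,7,1,1,1,AA
3,8,0,0,0,
3,9,0,0,0,
4,1,0,0,1,
4,2,0,0,1,
4,3,1,1,1,M
4,4,0,0,0,
4,5,1,1,1,PG
4,6,1,1,1,AA
4,7,0,0,0,
4,8,0,0,0,
4,9,0,0,0,
5,1,0,0,1,
5,2,0,0,1,
5,3,0,0,1,
5,4,0,0,1,
5,5,0,0,0,
5,6,1,1,1,AA
5,7,1,1,1,AA
5,8,0,0,0,
5,9,0,0,0,
6,1,0,0,1,
6,2,0,0,1,
6,3,0,0,1,
6,4,0,0,1,
6,5,0,0,1,
6,6,1,3,1,BC
6,7,1,1,1,BC
6,8,0,0,0,
6,9,0,0,0,
7,1,0,0,1,
7,2,0,0,1,
7,3,0,0,1,
7,4,0,0,1,
7,5,1,1,1,BC
7,6,1,1,1,BC
7,7,1,1,1,B
7,8,0,0,1,
7,9,0,0,0,
8,1,0,0,1,
8,2,0,0,1,
8,3,0,0,1,
8,4,0,0,1,
8,5,0,0,1,
8,6,1,1,1,B
8,7,0,0,1,
8,8,1,1,1,H
8,9,0,0,1,
9,1,0,0,1,
9,2,0,0,1,
9,3,0,0,1,
9,4,0,0,1,
9,5,0,0,1,
9,6,0,0,1,
9,7,0,0,1,
9,8,0,0,1,
9,9,0,0,1,
10,1,0,0,1,
10,2,0,0,1,
10,3,0,0,1,
10,4,0,0,1,
10,5,0,0,1,
10,6,0,0,1,
10,7,0,0,1,
10,8,0,0,1,
10,9,0,0,1,
11,1,0,0,1,
11,2,0,0,1,
11,3,0,0,1,
11,4,0,0,1,
11,5,0,0,1,
11,6,0,0,1,
11,7,0,0,1,
11,8,0,0,1,
11,9,0,0,1,
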