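label,code,longitude,latitude
1,10001A,116.37,39.87
2,10002A,116.17,40.29
3,10003A,116.43,39.95
4,10004A,116.43,39.87
5,10005A,116.47,39.97
6,10006A,116.36,39.94
7,10007A,116.32,39.99
8,10008A,116.72,40.14
9,10009A,116.64,40.39
10,10010A,116.23,40.20
11,10011A,116.41,40.00
12,10012A,116.22,39.93
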