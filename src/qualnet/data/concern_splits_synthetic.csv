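code_id,yes_count,no_count
1.1,4,1
1.2,4,0
1.4,3,0
1.5,2,2
1.6,0,3
1.7,6,0
2.2,0,2
2.4,2,1
2.6,2,0
2.7,7,0
3.2,6,0
3.3,7,0
3.4,5,3
3.5,5,1
4.1,3,2
4.4,3,0
5.1,3,1
5.2,4,4
5.3,2,0
6.1,6,0
6.3,0,2
6.4,5,4
6.5,0,7
7.3,4,2
7.4,3,2
7.5,8,0
7.6,0,4
7.7,2,0
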