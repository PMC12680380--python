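chromosome	length_bp	n_markers	length_cm	first_marker_bp	last_marker_bp
1	18983185	832	113.7	17062	18967069
2	17914192	537	114.8	7724	17912629
3	8228935	352	73.9	53699	8188299
4	11297323	393	79.3	91675	11270996
5	19970953	556	117.3	24704	19402653
6	19679654	593	119.9	11604	19662421
7	20256391	591	126.4	30989	20254110
8	21132631	800	123.8	42234	20550225
9	8250627	169	56.3	28785	8236420
10	8173407	235	57.4	11961	8106371
11	11083367	175	76.4	40210	11082329
12	14849823	415	76.2	59344	14818153
13	11692151	124	76.2	17912	11596382
14	8885846	320	58.1	23073	8431857
15	7690864	289	56.0	45077	7655559
16	8056988	199	53.5	44312	8044728
17	10678808	390	105.1	9100	10664610
18	11179804	423	82.2	22588	11176547
19	19485313	471	115.4	78773	19268726
20	16245370	538	106.5	93681	16240059
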