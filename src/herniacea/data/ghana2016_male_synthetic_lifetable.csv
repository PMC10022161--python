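age,q,ex
0,0.004085236317164509,63.67173089758701
1,0.004093506602945718,62.93086095438689
2,0.0041025105261343064,62.18747253713965
3,0.004112313158419978,61.44158855619693
4,0.004122985341780572,60.69323429881021
5,0.0041346041999091865,59.94243758298635
6,0.00414725369491975,59.18922891956653
7,0.004161025233334947,58.43364168279056
8,0.004176018325704023,57.6757122895948
9,0.004192341304589231,56.91548038787366
10,0.0042101121060657,56.15298905391281
11,0.004229459120341006,55.388284999175085
12,0.004250522117582034,54.62141878658816
13,0.004273453255577042,53.85244505644524
14,0.004298418176436836,53.0814227619859
15,0.004325597200165787,52.308415414673156
16,0.004355186623621332,51.533491339124524
17,0.004387400134115538,50.756723937588156
18,0.004422470347720919,49.978191963779956
19,0.004460650483212425,49.19797980581279
20,0.004502216183523422,48.416177777854486
21,0.004547467497619473,47.63288242004564
22,0.004596731036803803,46.84819680609223
23,0.004650362320670398,46.06223085781919
24,0.004708748329226409,45.27510166583083
25,0.004772310279109293,44.486933815270504
26,0.004841506643352922,43.69785971550544
27,0.004916836435799987,42.908019932382864
28,0.004998842783035751,42.11756352151045
29,0.005088116808640186,41.32664836080745
30,0.005185301856618141,40.535441480353605
31,0.005291098083097134,39.74411938733069
32,0.005406267447779611,38.952868383607886
33,0.0055316391392077335,38.161884873268036
34,0.005668115470661705,37.371375657108544
35,0.005816678286477139,36.58155821087987
36,0.005978395921725443,35.79266094374986
37,0.00615443076158928,35.0049234332041
38,0.006346047450361825,34.218596632317244
39,0.00655462180382782,33.43394304505907
40,0.006781650482842849,32.651236865038506
41,0.007028761490211921,31.870764072843095
42,0.007297725557484647,31.09282248690616
43,0.0075904684930147015,30.317721762636804
44,0.007909084567569558,29.5457833343844
45,0.008255851018899807,28.777340294688607
46,0.008633243761953846,28.01273720519574
47,0.00904395439682093,27.25232983361145
48,0.009490908611939908,26.49648481111767
49,0.009977286085566917,25.745579204818032
50,0.01050654199385348,24.99999999999999
51,0.011082430239045427,24.26014348732339
52,0.011709028516131648,23.526414550473397
53,0.012390765340580145,22.799225850359043
54,0.013132449163390625,22.07899690260491
55,0.013939299702314556,21.366153045878836
56,0.014816981619426572,20.661124299527884
57,0.0157716406749292,19.96434411006027
58,0.016809942484653284,19.276247987212884
59,0.01793911400368109,18.59727203167919
60,0.019166987850208983,17.927851358033852
61,0.02050204957144275,17.26841841796848
62,0.021953487936083982,16.619401230632324
63,0.023531248314785813,15.981221528633098
64,0.02524608917960014,15.354292830072872
65,0.027109641714488264,14.739018448841907
66,0.029134472479766638,14.135789457236266
67,0.03133414901200404,13.544982616763152
68,0.033723308165183874,12.966958294707974
69,0.03631772690639645,12.402058385611133
70,0.03913439516709394,11.850604258189021
71,0.04219159021583663,11.312894749378488
72,0.045508951856916835,10.789204228030439
73,0.049107557567339644,10.279780751268014
74,0.05300999645807114,9.784844336598658
75,0.05724044067961975,9.304585372465933
76,0.0618247125820548,8.839163188982155
77,0.06679034558042074,8.388704809026976
78,0.07216663626331132,7.953303897647147
79,0.07798468481030041,7.533019924644929
80,0.08427742024899754,7.127877551250788
81,0.09107960648163971,6.737866246623512
82,0.09842782434301922,6.362940133268676
83,0.10636042421732139,6.003018051767534
84,0.11491744294567097,5.657983823565348
85,0.1241404779082591,5.327686674485819
86,0.13407251028038325,5.011941758601042
87,0.14475766856448224,4.710530687808499
88,0.1562409226244158,4.423201919555544
89,0.16856769764110535,4.149670770663841
90,0.1817833967332949,3.8896186861025153
91,0.19593282052586836,3.6426911560698776
92,0.2110594718053317,3.4084932656065257
93,0.22720473370776217,3.1865811321190813
94,0.2444069107965926,2.976446155019708
95,0.26270012409338295,2.777486507493775
96,0.28211305384064345,2.5889555008988374
97,0.3026675277431409,2.409866953389526
98,0.3243769579135879,2.2388183246484976
99,0.347244637002329,2.0736516020513447
100,0.37126191326716673,1.9107831068972154
101,0.3964062758339243,1.7438327447732507
102,0.42263939521847926,1.5607118579500283
103,0.44990518027988513,1.33717394149435
104,0.4781279308896247,1.0218720691103753
105,1.0,0.5
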