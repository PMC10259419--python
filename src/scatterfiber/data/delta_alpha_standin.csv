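alpha_deg,delta_deg
0,180
1,179.9725851
2,179.8903489
3,179.7533163
4,179.561529
5,179.3150457
6,179.0139412
7,178.6583073
8,178.2482524
9,177.7839013
10,177.2653955
11,176.692893
12,176.0665681
13,175.3866117
14,174.6532307
15,173.8666487
16,173.0271053
17,172.1348561
18,171.1901729
19,170.1933436
20,169.1446717
21,168.0444768
22,166.8930938
23,165.6908736
24,164.4381824
25,163.1354017
26,161.7829283
27,160.3811744
28,158.9305667
29,157.4315473
30,155.8845727
31,154.2901141
32,152.6486573
33,150.9607022
34,149.2267631
35,147.447368
36,145.623059
37,143.7543918
38,141.8419356
39,139.8862731
40,137.8879998
41,135.8477244
42,133.7660686
43,131.6436663
44,129.4811641
45,127.2792206
46,125.0385067
47,122.7597048
48,120.4435091
49,118.0906252
50,115.7017697
51,113.2776704
52,110.8190656
53,108.3267042
54,105.8013454
55,103.2437585
56,100.6547226
57,98.0350263
58,95.38546756
59,92.70685348
60,90
61,87.26573164
62,84.5048813
63,81.71828995
64,78.90680642
65,76.07128711
66,73.21259575
67,70.33160313
68,67.42918681
69,64.50623092
70,61.5636258
71,58.6022678
72,55.62305899
73,52.62690685
74,49.61472405
75,46.58742812
76,43.54594121
77,40.49118978
78,37.42410435
79,34.34561917
80,31.25667198
81,28.15820371
82,25.05115817
83,21.93648181
84,18.81512339
85,15.68803369
86,12.55616527
87,9.420472124
88,6.281909406
89,3.141433159
90,0
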