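node,network
1,MF
2,MF
3,MF
4,MF
5,MF
6,MF
7,MF
8,MF
9,MF
10,MF
11,MF
12,MF
13,MF
14,MF
15,MF
16,MF
17,MF
18,MF
19,MF
20,MF
21,MF
22,MF
23,MF
24,MF
25,MF
26,MF
27,MF
28,MF
29,MF
30,FP
31,FP
32,FP
33,FP
34,FP
35,FP
36,FP
37,FP
38,FP
39,FP
40,FP
41,FP
42,FP
43,FP
44,FP
45,FP
46,FP
47,FP
48,FP
49,FP
50,FP
51,FP
52,FP
53,FP
54,FP
55,FP
56,FP
57,FP
58,FP
59,FP
60,FP
61,FP
62,FP
63,FP
64,DM
65,DM
66,DM
67,DM
68,DM
69,DM
70,DM
71,DM
72,DM
73,DM
74,DM
75,DM
76,DM
77,DM
78,DM
79,DM
80,DM
81,DM
82,DM
83,DM
84,MOT
85,MOT
86,MOT
87,MOT
88,MOT
89,MOT
90,MOT
91,MOT
92,MOT
93,MOT
94,MOT
95,MOT
96,MOT
97,MOT
98,MOT
99,MOT
100,MOT
101,MOT
102,MOT
103,MOT
104,MOT
105,MOT
106,MOT
107,MOT
108,MOT
109,MOT
110,MOT
111,MOT
112,MOT
113,MOT
114,MOT
115,MOT
116,MOT
117,MOT
118,MOT
119,MOT
120,MOT
121,MOT
122,MOT
123,MOT
124,MOT
125,MOT
126,MOT
127,MOT
128,MOT
129,MOT
130,MOT
131,MOT
132,MOT
133,MOT
134,V1
135,V1
136,V1
137,V1
138,V1
139,V1
140,V1
141,V1
142,V1
143,V1
144,V1
145,V1
146,V1
147,V1
148,V1
149,V1
150,V1
151,V1
152,V2
153,V2
154,V2
155,V2
156,V2
157,V2
158,V2
159,V2
160,V2
161,VA
162,VA
163,VA
164,VA
165,VA
166,VA
167,VA
168,VA
169,VA
170,VA
171,VA
172,VA
173,VA
174,VA
175,VA
176,VA
177,VA
178,VA
179,LIM
180,LIM
181,LIM
182,LIM
183,LIM
184,LIM
185,LIM
186,LIM
187,LIM
188,LIM
189,LIM
190,LIM
191,LIM
192,LIM
193,LIM
194,LIM
195,LIM
196,LIM
197,LIM
198,BG
199,BG
200,BG
201,BG
202,BG
203,BG
204,BG
205,BG
206,BG
207,BG
208,BG
209,BG
210,BG
211,BG
212,BG
213,BG
214,BG
215,BG
216,BG
217,BG
218,BG
219,BG
220,BG
221,BG
222,BG
223,BG
224,BG
225,CER
226,CER
227,CER
228,CER
229,CER
230,CER
231,CER
232,CER
233,CER
234,CER
235,CER
236,CER
237,CER
238,CER
239,CER
240,CER
241,CER
242,CER
243,CER
244,CER
245,CER
246,CER
247,CER
248,CER
249,CER
250,CER
251,CER
252,CER
253,CER
254,CER
255,CER
256,CER
257,CER
258,CER
259,CER
260,CER
261,CER
262,CER
263,CER
264,CER
265,CER
266,CER
267,CER
268,CER
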