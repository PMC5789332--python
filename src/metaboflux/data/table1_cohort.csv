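Case,G,Age,Working Clinical Form,Clinical Form,P.T.,Actual EDSS,OCGB IgG,OCMB IgM,Ac-AQ4,T
1,F,23,RMS (G+/M−),RRMS,5,1.50,G+,M-,N.A.,"IFN, FGM"
2,F,21,RMS (G+/M−),SPMS,18,4.00,G+,M-,N.A.,"IFN, MTZ"
3,F,36,RMS (G+/M−),CIS,4,1.50,G+,M-,N.A.,N.T.
4,M,22,RMS (G+/M−),RRMS,6,1.50,G+,M-,N.A.,"IFN, CPX, NTZ, FGM"
5,F,21,RMS (G+/M−),RRMS,3,3.00,G+,M-,N.A.,IFN
6,F,30,RMS (G+/M−),RRMS,22,4.00,G+,M-,N.A.,"IFN, NTZ, FGM"
7,F,29,RMS (G+/M−),RRMS,10,1.50,G+,M-,N.A.,N.T.
8,F,29,RMS (G+/M−),RRMS,7,1.50,G+,M-,N.A.,"IFN, NTZ"
9,F,28,RMS (G+/M−),RRMS,10,5.50,G+,M-,N.A.,"MTZ, IFN"
10,F,28,RMS (G+/M−),RRMS,4,1.00,G+,M-,N.A.,N.T.
11,F,37,RMS (G+/M+),RRMS,7,3.50,G++,M+,N.A.,"IFN, NTZ, CPX"
12,M,32,RMS (G+/M+),RRMS,4,1.00,G+,M+,N.A.,IV-IgG
13,F,44,RMS (G+/M+),RRMS,5,2.00,G+,M+,N.A.,N.T.
14,F,26,RMS (G+/M+),RRMS,5,2.00,G++,M++,N.A.,U.
15,F,14,RMS (G+/M+),RRMS,18,3.50,G+,M+,N.A.,"PE, IFN, NTZ, ASCT"
16,M,25,RMS (G+/M+),RRMS,11,2.00,G+,M+,N.A.,"IFN, FGM"
17,F,21,RMS (G+/M+),SPMS,25,8.50,G++,M+,N.A.,"IFN, AZA, MTZ, IV-IgG"
18,F,17,RMS (G+/M+),RRMS,16,2.00,G+,M+,N.A.,U.
19,F,23,RMS (G+/M+),SPMS,18,6.50,G+,M+,N.A.,"IFN, IV-IgG, Cy"
20,F,22,RMS (G+/M+),SPMS,5,4.00,G+,M+,N.A.,"IFN, FGM, CPX"
21,F,29,RMS (G+/M+),RRMS,5,2.50,G+,M+,N.A.,"IFN, FGM, CPX"
22,M,39,Spinal MS,SPMS,10,4.50,G+,M+,N.A.,"IFN, Cy, FGM, NTZ"
23,F,25,Spinal MS,SPMS,6,7.00,G+,M-,N.A.,"IFN, MTZ, RTX"
24,F,25,Spinal MS,SPMS,14,8.00,G+,M+,N.A.,"IFN, Cy, RTX"
25,M,34,Spinal MS,SPMS,9,6.00,G+,M-,N.A.,"IFN, Cy"
26,M,34,Spinal MS,SPMS,6,6.50,G+,N.A.,N.A.,"IFN, MTZ, IV-IgG"
27,F,23,Spinal MS,RRMS,5,4.00,G-,M-,N.A.,"IFN, NTZ, FGM, RTX"
28,F,40,Spinal MS,SPMS,10,7.50,G-,M+,N.A.,"AZA, IV-IgG, Cy, RTX"
29,F,23,Spinal MS,SPMS,28,6.50,G+,M-,N.A.,"IFN, MTZ, RTX"
30,F,54,PPMS,PPMS,12,7.00,G+,M-,N.A.,N.T.
31,M,40,PPMS,PPMS,23,6.00,G+,M-,N.A.,"MTZ, Cy, RTX"
32,F,52,PPMS,PPMS,14,5.50,G++,M-,N.A.,AZA
33,F,38,PPMS,PPMS,11,5.50,G+,M-,N.A.,N.T.
34,M,31,PPMS,PPMS,24,6.00,G+,M-,N.A.,N.T.
35,F,47,PPMS,PPMS,14,5.50,G++,M-,N.A.,N.T.
36,M,49,PPMS,PPMS,11,6.00,G-,M-,N.A.,FGM
37,F,26,PPMS,PPMS,13,6.50,G++,M-,N.A.,N.T.
38,F,34,PPMS,PPMS,6,5.00,G++,M-,N.A.,N.T.
39,F,39,PPMS,PPMS,8,8.50,G-,M-,N.A.,Cy
40,M,18,PPMS,PPMS,15,8.00,U.,U.,N.A.,U.
41,F,39,NMO,NMO,5,9.00,G-,M-,P.,"IFN, MTZ, Cy, RTX"
42,F,50,NMO,NMO,4,7.00,G-,M-,P.,"IFN, NTZ, RTX"
43,M,15,NMO,NMO,17,4.00,G+,M+,N.,"IFN, IV-IgG"
44,M,42,NMO,NMO,5,3.50,N.A.,N.A.,P.,IV-IgG
45,F,22,NMO,NMO,5,2.50,G+,M+,P.,"IV-IgG, IFN, CPX"
46,F,27,NMO,NMO,5,2.00,G+,M-,N.,"IFN, AZA"
47,M,9,NMO,NMO,14,1.00,G-,M-,N.,"IV-IgG, IFN, CPX"
48,F,8,NMO,NMO,32,4.00,G+,M+,N.,"IFN, IV-IgG"
49,M,19,NMO,NMO,20,8.50,G-,M-,N.,"IFN, MTZ, Cy, RTX"
50,M,23,CONTROL,Non-inflammatory motor neuron neurological disease,N.A.,N.A.,G-,M-,N.A.,N.T.
51,F,77,CONTROL,Glioblastoma,N.A.,N.A.,G-,M-,N.A.,N.T.
52,F,33,CONTROL,Central Pontine myelinolisis,N.A.,N.A.,G-,M-,N.A.,N.T.
53,F,32,CONTROL,Central Pontine myelinolisis,N.A.,N.A.,G-,M-,N.A.,N.T.
54,M,59,CONTROL,Classic migraine,N.A.,N.A.,G-,M-,N.A.,N.T.
55,F,36,CONTROL,Headache in which subarachnoid hemorrhage was suspected,N.A.,N.A.,G-,M-,N.A.,N.T.
56,F,57,CONTROL,Headache in which subarachnoid hemorrhage was suspected,N.A.,N.A.,G-,M-,N.A.,N.T.
57,M,37,CONTROL,Headache in which subarachnoid hemorrhage was suspected,N.A.,N.A.,G-,M-,N.A.,N.T.
58,F,21,CONTROL,Benign intracranial hypertension,N.A.,N.A.,G-,M-,N.A.,N.T.
59,M,13,CONTROL,Chronic axonal polyneuropathy,N.A.,N.A.,G-,M-,N.A.,N.T.
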