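id,sequence,pic50,test
1,GLRKRLRKFRNKIKEKLKKI,5.3979,0
2,GLRKALRKFRNKIKEALKKI,5.6990,0
3,GLRKRLRKARNKIKEKLKKI,5.3979,0
4,GLRKRLRKFRNKIKQKLKKI,5.3979,0
5,FLGGLMKAFPALICAVTKKC,5.1549,1
6,FLGGLFKLVPSVICAVTKKC,4.9031,0
7,FLGGLMKIIPAAFCAVTKKC,5.0458,0
8,AALRGCWTKSIPPKPCPGKR,4.3354,0
9,FLPIIAGMAAKVICAITKKC,4.3010,1
10,FFPIIAGMAAKVICAITKKC,4.8861,0
11,IASKVANTVQKLKRKAKNAV,4.6021,0
12,PRPPRLPRPRPRPLPFPRPG,4.7423,0
13,FLPFLLSALPKVFCFFSKKC,4.7959,0
14,FLPLLLSALPSFLCLVFKKC,4.4815,0
15,GRFRRLRKKTRKRLKKIGKV,4.4949,1
16,PRLPPRIPPGFPPRFPPRFP,5.3010,1
17,GLRRALLRLLRSLRRLLLRA,5.0969,0
18,LAKRRVLTLLRQLRRVSPSS,4.8539,0
19,KRFWQLVPLAIKIYRAWKRR,5.6990,1
20,PMLRVRLASHLRKLRKRLLR,5.2041,1
21,KIAKVALKALKIAKVALKAL,5.8239,0
22,KIAKVALKALKIAKGALKAL,6.1249,0
23,FRIRVRVFKRIVQRIKDFLR,6.0000,0
24,FRIRVRVAKKFGKAFVGEIM,5.0969,0
25,KKRYKKKYKAYKPYKKKKKF,4.9031,1
26,SPRRRTPSPRRRRSQSPRRR,4.6021,0
27,RPRRRATTRRRITTGTRRRR,4.9031,0
28,RRLTLRQLLGLGSRRRRRSR,4.6021,0
29,GRRGPRRANQNGTRRRRRRT,4.6021,0
30,WRRRYRRWRRRRRWRRRPRR,5.5045,1
31,IVPFLLGMVPKLVCLITKKC,4.1938,0
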