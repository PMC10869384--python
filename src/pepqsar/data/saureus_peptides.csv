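id,sequence,pic50,test
1,GLRKRLRKFRNKIKEKLKKI,5.3979,0
2,GLRKALRKFRNKIKEALKKI,5.6990,0
3,GLRKRLRKARNKIKEKLKKI,5.0969,0
4,GLRKRLRKFRNKIKQKLKKI,5.3979,0
5,AALKGCWTKSIPPKPCSGKR,4.9318,1
6,AALRGCWTKSIPPKPCSGKR,5.2366,0
7,AALRGCWTKSIPPKPCPGKR,5.2366,0
8,SALVGCWTKSYPPNPCFGRG,4.9318,0
9,SALVGCWTKSWPPKPCFGRG,4.6383,1
10,GRFRRLRKKTRKRLKKIGKV,5.2218,0
11,KLLLKLKLKLLKGWKRKRFG,5.3979,1
12,GAPKGCWTKSYPPQPCFGKK,4.7258,1
13,FFFHIVKGLFHAGRMIHGLV,5.9031,0
14,RPRRRATTRRRITTGTRRRR,4.3010,0
15,RRLTLRQLLGLGSRRRRRSR,5.5045,1
16,WRRRYRRWRRRRRWRRRPRR,5.8069,0
17,KIAKGALKALKIAKVALKAL,4.4949,1
18,KIGKALGKALKALGKALGKA,4.7959,0
19,KIALKALKALKALGKALKAL,5.3979,1
20,GLYNFIKVLGRTVFGLYKQF,4.7959,0
21,GILSKLGKALKKAAKHAAKA,5.0969,0
22,CKILSKTIKCRIPCGRRKEY,5.5229,1
23,GLLDFLKAAGKGLVSNLLEK,4.8239,0
24,YYHFWHRGVTKRSLSPHRPR,5.2218,0
25,KIGVLKKYFKIGALIKAIIK,5.0969,0
26,KKKFIYIVLALIKGAIIKKG,4.1938,0
27,KGKKGVIIAILLFAIIYKKK,3.8928,0
28,LKKLKQLLGKLSEFAAAFVA,4.4949,0
29,GQLNKFIKKAQRKFHEKFAK,3.8928,0
30,KVFKSVVKLLEKTVLKKFSK,4.1938,0
31,KAAKTVFKLFKLQAKRAIEA,3.8928,1
32,WCRRYRVLVRGVLVRYRRCW,5.3979,1
33,FLREFHKWIERVVGWLGKVF,4.4949,0
34,RQYMRQIEQALRYGYRISRR,4.0000,0
35,GSKKPVPIIYCNRRGKCQRM,4.9830,0
36,GSKKPVPIIYCNRRTKCQRM,4.6819,0
37,VGKTWIKVIRGIGKSKIKWQ,5.5528,0
38,KIAKVALKALKIAKVALKAL,5.8239,0
39,KIAKVALKALKIAKGALKAL,5.5229,0
40,FIVPSIFLLKKAFCIALKKC,5.0969,0
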