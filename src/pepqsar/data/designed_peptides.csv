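id,sequence,pred_ecoli_comfa,pred_ecoli_svr,pred_saureus_comfa,pred_saureus_svr
D1,KLAKAALRARRIDWGDLLRL,6.244,6.245,5.913,5.916
D2,KIAKVALRARRIDRGDLLRL,6.237,6.240,5.913,5.915
D3,KLAKAALRARRIDWGDFFRL,6.233,6.235,5.904,5.910
D4,KIAKAAIRARRIDWGDFFRL,6.238,6.237,5.915,5.917
D5,KLAKAALRARKIDHGDLLRL,6.241,6.242,5.914,5.916
D6,KLFRAALRARKIDWGDLLRL,6.242,6.240,5.913,5.914
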