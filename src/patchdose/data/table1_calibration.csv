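nahs_uM,current_nA,sem_nA,h2s_uM
10,13.67,0.33,2
48.7,88.67,2.4,11
95.23,183.33,9.61,21
170.2,303.33,11.02,38
226,359.33,11.66,51
300,394.00,8.62,67
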