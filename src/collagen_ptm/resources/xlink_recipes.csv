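name,components,n_water,n_h2,n_hexose
LNL,Lysald;K,1,1,0
HLNL,Lysald;Hyl,1,1,0
G-HLNL,Lysald;Hyl,1,1,1
GG-HLNL,Lysald;Hyl,1,1,2
HHMD,Lysald;Lysald;H;Hyl,2,1,0
d-HHMD,Lysald;Lysald;H;K,2,1,0
ACP,Lysald;Lysald,1,0,0
dehydro-LNL,Lysald;K,1,0,0
dehydro-HLNL,Lysald;Hyl,1,0,0
dehydro-HHMD,Lysald;Lysald;H;Hyl,2,0,0
dehydro-d-HHMD,Lysald;Lysald;H;K,2,0,0
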