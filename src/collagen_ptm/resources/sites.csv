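chain,label,sequence,pyro_glu,mod_positions,allowed_states,hyp_mode,synthetic
alpha1(I),Lys-87,GEPGPAGSKGDSGAPGER,no,9,Lys|Hyl|G-Hyl|GG-Hyl,auto,yes
alpha1(I),Lys-99,GLPGAKGEAGTPGVR,no,6,Lys|Hyl|G-Hyl|GG-Hyl,auto,yes
alpha1(I),Lys-174,GNDGAKGDAGAPGER,no,6,Lys|Hyl|G-Hyl|GG-Hyl,auto,yes
alpha1(I),Lys-219,GEAGPSGPKGETGPR,no,9,Lys|Hyl,auto,yes
alpha1(I),Lys-564,GSPGEAGKPGEQGVR,no,8,Lys|Hyl|G-Hyl|GG-Hyl,auto,yes
alpha1(I),Lys-603,GAPGDKGEAGPSGPR,no,6,Lys|Hyl|G-Hyl|GG-Hyl,auto,yes
alpha2(I),Lys-87,GFPGSKGETGPAGVR,no,6,Lys|Hyl,auto,yes
alpha2(I),Lys-174,GDVGAKGDSGAPGER,no,6,Lys|Hyl|G-Hyl|GG-Hyl,auto,yes
alpha2(I),Lys-219,GTAGPKGSTGDPGSR,no,6,Lys|Hyl|G-Hyl|GG-Hyl,auto,yes
alpha2(I),Lys-933,GSAGSKGDQGETGHR,no,6,Lys|Hyl|G-Hyl|GG-Hyl,auto,yes
alpha1(I),Lys-918/930,GDKGETGEQGDRGIKGHR,no,3;15,Lys|Hyl;Lys|Hyl,none,no
alpha1(I),Lys-9^N,QLSYGYDEKSTGISVPGPMGPSGPR,yes,9,Lys|Lysald|Hyl,none,yes
alpha1(I),Lys-16^C,SAGFDFSFLPQPPQEKAHDGGR,no,16,Lys|Lysald|Hyl,none,yes
alpha2(I),Lys-5^N,QYSDKGVSSGPGPM,yes,5,Lys|Lysald|Hyl,none,no
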