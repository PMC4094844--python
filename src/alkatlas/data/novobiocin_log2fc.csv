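gene,WT_novobiocin,WT_novobiocin_HS,WT_novobiocin_LT,WT_novobiocin_salt_stress
ado,0.09,-2.54,-1.57,-1.16
aar,-0.16,-2.24,-0.10,-1.13
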