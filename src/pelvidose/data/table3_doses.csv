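label,esak_mGy,kap_Gycm2,kfia_mGy,e_mSv,h_testes_mGy,h_ovaries_mGy
"1905 Beck, Biddle, Albers-Schoenberg",341,173,,11.4,149,13
"1958 Janker, Lincoln",25,15.4,,1.32,15,2.1
"2010 European DRL",5.4,3.0,,0.52,4.5,1.2
"2017 Dutch target DRL",2.7,1.5,,0.26,2.3,0.61
"2018 MUMC+",0.82,0.55,,0.095,0.74,0.24
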