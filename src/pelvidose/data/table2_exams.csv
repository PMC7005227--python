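room,kvp,ma_tube_current,t_exposure_ms,tube_load_mAs,kap_Gycm2,fid_cm,kfia_mGy,esak_mGy
room1,81,806,20,16,0.48,126,0.52,0.78
room2,85,472,49,23,0.70,142,0.61,0.91
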