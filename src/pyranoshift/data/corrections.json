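{
 "version": 1,
 "description": "Default empirical correction factors (gathered modeling set): offset = mean(exp - calc), corrected = calc + offset.",
 "scope": "gathered",
 "factors": [
  {
   "class": "C1_C8",
   "offset_ppm": -2.9
  },
  {
   "class": "pyran_olefinic_1p",
   "offset_ppm": -3.7
  },
  {
   "class": "pyran_olefinic_2p",
   "offset_ppm": 2.8
  }
 ]
}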