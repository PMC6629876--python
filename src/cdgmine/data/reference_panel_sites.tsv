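reference_name	position	canonical	alternates
PleD	327	D	
PleD	332	K	
PleD	335	N	
PleD	344	D	
PleD	370	D	
PleD	442	K	
PleD	446	R	
TBD_1265	523	E	
TBD_1265	527	R	
TBD_1265	546	E	
TBD_1265	584	N	
TBD_1265	616	E	
TBD_1265	646	D	
TBD_1265	647	D	
TBD_1265	703	E	
TBD_1265	723	Q	
Bd1817	183	H	
Bd1817	184	D	
Bd1817	212	H	
Bd1817	237	H	
Bd1817	238	E	H
Bd1817	265	N	E
Bd1817	269	N	R
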