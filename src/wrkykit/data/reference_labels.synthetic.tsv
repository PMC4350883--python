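# Synthetic reference labels: ref_id -> group
ref_id	group
I_CT	I_CT
IIc	IIc
IId	IId
IIe	IIe
I_NT	I_NT
IIb	IIb
IIa	IIa
III	III
III_MOSS	III_MOSS_VARIANT
FUNGAL	FUNGAL_TYPE
ALGAL	ALGAL_SINGLE
DIPLO_NT	DIPLOMONAD_TYPE
DIPLO_CT	DIPLOMONAD_TYPE
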