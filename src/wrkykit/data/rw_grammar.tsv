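# Architecture grammar for the eight chimeric R-protein/WRKY families.
# Pattern tokens are matched in order against the full architecture string;
# [token] is optional (0 or 1 occurrences).  WRKY(group) constrains the WRKY
# domain's group call; in the RW7 rule an UNCLASSIFIED (truncated) WRKY token
# matches any required WRKY(group).
family	pattern
RW1	TIR NB-ARC LRR WRKY(IIe)
RW2	TIR NB-ARC LRR WRKY(III) [WRKY(III)]
RW3	PAH WRKY(I_NT) WRKY(I_CT) NB-ARC [MAPKKK]
RW4	TIR NB-ARC LRR WRKY(III)
RW5	[B3] LRR NB-ARC LRR WRKY(IIe)
RW6	NB-ARC LRR WRKY(III) [WRKY(III)] [NAC]
RW7	LRR WRKY(III) WRKY(IId) CAMB WRKY(IIc)
RW8	WRKY(III) NB-ARC LRR
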