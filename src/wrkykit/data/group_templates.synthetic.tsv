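# Synthetic WRKY group domain templates (designed, not transcribed from any
# published alignment).  75 residues each; diagnostics satisfy the documented
# group rules.  mask: 1 = diagnostic position (never mutated by the simulator).
# chelators: 0-based template indices; pr/vqr_anchor: 1-based residue of the
# anchor R, or -1.
template_id	group	signature_variant	finger_class	template	mask	sig_offset	chelators	pr_anchor	vqr_anchor
I_CT	I_CT	WRKYGQK	C2H2_X4	DLQEVRAIWRKYGQKTRESFQDANQADQYLDDKFDVPPENQPRCSKPQCEPIFRSNVFDFPMEFQRQYQMRHIHV	000000001111111000000000000000000000000001110000100000000000000000000001010	8	43,48,71,73	43	-1
IIc	IIc	WRKYGQK	C2H2_X4	FLEEVRFIWRKYGQKTREGFMDANYDDQYPDDKFDVPPENQPRCVKPQCEPRFRSRVFDNDMERQGIYQMRHIHV	000000001111111000000000000000000000000001110000100000000000000000000001010	8	43,48,71,73	43	-1
IId	IId	WRKYGQK	C2H2_X4	DLLEVEMVWRKYGQKTFESQQDANQAMQYLRDKKDVTIDNNPRCSKIQCEPFFRFNMMDFFEEMFRQGQYRHEHS	000000001111111000000000000000000000000001110000100000000000000000000001010	8	43,48,71,73	43	-1
IIe	IIe	WRKYGQK	C2H2_X4	DLQEVLAIWRKYGQKQRESSGQAVQTLNAKIQKFDVNTEDEPRCSVPMCVGIFRSNVFDMPGEEQRQDQMSHDHV	000000001111111000000000000000000000000001110000100000000000000000000001010	8	43,48,71,73	43	-1
I_NT	I_NT	WRKYGQK	C2H2_X4	FQQPKTRDWRKYGQKRQMFAPTGDNPLFYQSYIQEQMDPYNEQCLNGMCFEMSDAINDFKGPVTFESSRIMHMHM	000000001111111000000000000000000000000000010000100000000000000000000001010	8	43,48,71,73	-1	-1
IIb	IIb	WRKYGQK	C2H2_X5	AFLSIDGCWRKYGQKKLMAGSEYYIMPVNIKAEIGIDLPKSICMENLACGMQRKDGNQVQRVDASGMGYIYHLHK	000001111111111000000000000000000000000000100000100000000111100000000001010	8	42,48,71,73	-1	61
IIa	IIa	WRKYGQK	C2H2_X5	ARLSQDGCWRKYGQKKLMAGSEYYIMPVNIKAEIGYDLPKSICMENLACGMQRKDGNQVQRFAASGMGYIDHLHK	000001111111111000000000000000000000000000100000100000000111100000000001010	8	42,48,71,73	-1	61
III	III	WRKYGQK	C2HC	DEYPEQGVWRKYGQKAGEMYNTSLLSFERDMAMQQGLYEPRCQQLAGCLADADYPDVQRGPIRDKGGAYGHGRCA	000000001111111000000000000000000000000111000001000000000000000000000010010	8	41,47,70,73	41	-1
III_MOSS	III_MOSS_VARIANT	WKKYGNK	C2HC	VEYPEQGVWKKYGNKAGEMYNMKLLSMERYDRLQQGLTDPRCQQLFMCLADADYPDVQIGPIRDKGGAYNHGVCA	000000001111111000000000000000000000000111000001000000000000000000000010010	8	41,47,70,73	41	-1
FUNGAL	FUNGAL_TYPE	WKNNGNT	FUNGAL	YPDLRQSAWKNNGNTMMSQYKSKLNLGKTQKIPAPKNQSEILPNTNETKCARFTRFCPLDQKPSAIEKQHMDRCS	000000001111111000000000000000000000000000000000010000001000000000000100010	8	49,56,69,73	-1	-1
ALGAL	ALGAL_SINGLE	WRKYGQK	C2H2_X4	DGEIRETNWRKYGQKFKMNRDSFGDIKRIVYAFSMQMYAPGFQCATLICRKALSQLTTRYFKNMYKPGAFTHMHK	000000001111111000000000000000000000000000010000100000000000000000000001010	8	43,48,71,73	-1	-1
DIPLO_NT	DIPLOMONAD_TYPE	WRKYGQK	C2H2_X4	GQIRRAIMWRKYGQKVKVLRGRFVTSIPTQMRPVSNYVNELQECQQESCITRNKAAYAYTRFRYQEYYDPSHNHQ	000000001111111000000000000000000000000000010000100000000000000000000001010	8	43,48,71,73	-1	-1
DIPLO_CT	DIPLOMONAD_TYPE	WKKYGHK	C2H2_X4	ALGTYLEMWKKYGHKDLVGYRPVFAVDDMAGNQTPDMVKANFDCKSDACIMDKTKQGNSEEYAQKVQQFNTHYHK	000000001111111000000000000000000000000000010000100000000000000000000001010	8	43,48,71,73	-1	-1
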