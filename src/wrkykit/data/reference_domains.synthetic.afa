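>I_CT
WRKYGQKTRESFQDANQADQYLDDKFDVPPENQPRCSKPQCEPIFRSNVFDFPMEFQRQYQMRHIH
>IIc
WRKYGQKTREGFMDANYDDQYPDDKFDVPPENQPRCVKPQCEPRFRSRVFDNDMERQGIYQMRHIH
>IId
WRKYGQKTFESQQDANQAMQYLRDKKDVTIDNNPRCSKIQCEPFFRFNMMDFFEEMFRQGQYRHEH
>IIe
WRKYGQKQRESSGQAVQTLNAKIQKFDVNTEDEPRCSVPMCVGIFRSNVFDMPGEEQRQDQMSHDH
>I_NT
WRKYGQKRQMFAPTGDNPLFYQSYIQEQMDPYNEQCLNGMCFEMSDAINDFKGPVTFESSRIMHMH
>IIb
WRKYGQKKLMAGSEYYIMPVNIKAEIGIDLPKSICMENLACGMQRKDGNQVQRVDASGMGYIYHLH
>IIa
WRKYGQKKLMAGSEYYIMPVNIKAEIGYDLPKSICMENLACGMQRKDGNQVQRFAASGMGYIDHLH
>III
WRKYGQKAGEMYNTSLLSFERDMAMQQGLYEPRCQQLAGCLADADYPDVQRGPIRDKGGAYGHGRC
>III_MOSS
WKKYGNKAGEMYNMKLLSMERYDRLQQGLTDPRCQQLFMCLADADYPDVQIGPIRDKGGAYNHGVC
>FUNGAL
WKNNGNTMMSQYKSKLNLGKTQKIPAPKNQSEILPNTNETKCARFTRFCPLDQKPSAIEKQHMDRC
>ALGAL
WRKYGQKFKMNRDSFGDIKRIVYAFSMQMYAPGFQCATLICRKALSQLTTRYFKNMYKPGAFTHMH
>DIPLO_NT
WRKYGQKVKVLRGRFVTSIPTQMRPVSNYVNELQECQQESCITRNKAAYAYTRFRYQEYYDPSHNH
>DIPLO_CT
WKKYGHKDLVGYRPVFAVDDMAGNQTPDMVKANFDCKSDACIMDKTKQGNSEEYAQKVQQFNTHYH
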