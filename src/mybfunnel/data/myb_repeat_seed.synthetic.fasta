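>seed1
GKGRWTAEEDELLRKAIEAYGEGKWSTIARLAGLKRCGKSCRLRWLNYLRPN
>seed2
GKGAWTPEEDELLRNAIEAYGGGKWSTVARLSGLKRCGKSCRLRWLNYLRPD
>seed3
KKGPWTAEEDQLLRDAVEKYGEGKWHLVPLRAGLNRCGKSCRLRWLNYLRPN
>seed4
GKGRWTAEEDALLRQCIEKYGEGKWHQVPYRAGLNRCRKSCRLRWLNYLKPS
>seed5
GKGRWSAEEDELLRKAIESYGEGKWREVPQRAGLNRCGKSCRLRWTNYLRPD
>seed6
GKTRWTPEEDEKLVAYIQKYGPGNWRAVPKNAGLKRCGKSCRLRWLNYLRPN
>seed7
GKGGWTAEEDKILIDYIQKHGEGNWRNLPKRAGLKRCGKSCRLRWANYLRPD
>seed8
GKSRWTAEEDELLRKHIEEYGEGKWSTIARSAGLQRCGKSCRLRWLNYLRPN
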