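time_s,ca_nb1,ca_nb2,ca_nb3
0.0,1.0030471707975444,0.989600158937595,1.0075045119580646
1.0,1.0094056471639121,0.9804896481134616,0.9869782049313768
2.0,1.001278404031673,0.9968375740765641,0.9998319884249571
3.0,0.9914695607242642,1.0087939797486283,1.0077779193542895
4.0,1.0006603457561316,1.0112724120696803,1.0046750934225204
5.0,1.015443815669401,1.003687507840825,0.99041117399171
6.0,1.2359506645347171,0.9995139062117038,0.9981513763645474
7.0,1.5315445812371107,1.047158432349423,0.998454705179312
8.0,1.7813277951897588,1.2176175636874793,1.0055169429036788
9.0,1.91753679588097,1.4679314819618325,1.0491751421912334
10.0,1.961866268220769,1.6375969390644431,1.203421753214919
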