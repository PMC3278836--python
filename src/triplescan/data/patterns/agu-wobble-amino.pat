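NAME agu-wobble-amino
CONVENTION glyN-centroid-L2.0-v1
SLOTS A G U
CHIRALITY 0
SOURCE A:3 A:1 A:2
B1X B1Y SS=27 SE=27 ES=27 EE=27
B1X B2X SS=87 SE=96 ES=54 EE=58
B1X B2Y SS=70 SE=109 ES=33 EE=73
B1X B3X SS=123 SE=136 ES=90 EE=100
B1X B3Y SS=112 SE=147 ES=76 EE=113
B1Y B2X SS=81 SE=79 ES=63 EE=79
B1Y B2Y SS=58 SE=98 ES=52 EE=87
B1Y B3X SS=99 SE=114 ES=117 EE=124
B1Y B3Y SS=90 SE=123 ES=101 EE=139
B2X B2Y SS=27 SE=27 ES=27 EE=27
B2X B3X SS=89 SE=82 ES=52 EE=47
B2X B3Y SS=66 SE=104 ES=28 EE=68
B2Y B3X SS=72 SE=74 ES=75 EE=61
B2Y B3Y SS=52 SE=92 ES=50 EE=84
B3X B3Y SS=24 SE=24 ES=24 EE=24
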