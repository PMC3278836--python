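NAME acc-protonated
CONVENTION glyN-centroid-L2.0-v1
SLOTS A C C
CHIRALITY 0
SOURCE A:1 A:2 A:3
B1X B1Y SS=27 SE=27 ES=27 EE=27
B1X B2X SS=85 SE=61 ES=67 EE=53
B1X B2Y SS=66 SE=84 ES=43 EE=77
B1X B3X SS=90 SE=77 ES=53 EE=43
B1X B3Y SS=66 SE=101 ES=28 EE=65
B1Y B2X SS=92 SE=74 ES=58 EE=35
B1Y B2Y SS=69 SE=98 ES=39 EE=59
B1Y B3X SS=74 SE=55 ES=75 EE=70
B1Y B3Y SS=51 SE=79 ES=52 EE=91
B2X B2Y SS=24 SE=24 ES=24 EE=24
B2X B3X SS=75 SE=90 ES=81 EE=88
B2X B3Y SS=66 SE=99 ES=64 EE=103
B2Y B3X SS=58 SE=68 ES=96 EE=108
B2Y B3Y SS=44 SE=80 ES=83 EE=120
B3X B3Y SS=24 SE=24 ES=24 EE=24
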