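NAME uau-hoogsteen-wc
CONVENTION glyN-centroid-L2.0-v1
SLOTS A U U
CHIRALITY 0
SOURCE A:1 A:2 A:3
B1X B1Y SS=27 SE=27 ES=27 EE=27
B1X B2X SS=89 SE=76 ES=55 EE=39
B1X B2Y SS=65 SE=100 ES=32 EE=63
B1X B3X SS=68 SE=58 ES=76 EE=53
B1X B3Y SS=44 SE=81 ES=56 EE=77
B1Y B2X SS=66 SE=60 ES=82 EE=61
B1Y B2Y SS=42 SE=81 ES=59 EE=86
B1Y B3X SS=90 SE=72 ES=51 EE=33
B1Y B3Y SS=66 SE=97 ES=28 EE=57
B2X B2Y SS=24 SE=24 ES=24 EE=24
B2X B3X SS=126 SE=99 ES=101 EE=74
B2X B3Y SS=109 SE=120 ES=86 EE=93
B2Y B3X SS=106 SE=81 ES=124 EE=96
B2Y B3Y SS=87 SE=104 ES=110 EE=113
B3X B3Y SS=24 SE=24 ES=24 EE=24
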