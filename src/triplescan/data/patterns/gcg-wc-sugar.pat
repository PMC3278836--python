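NAME gcg-wc-sugar
CONVENTION glyN-centroid-L2.0-v1
SLOTS C G G
CHIRALITY 0
SOURCE A:2 A:1 A:3
B1X B1Y SS=24 SE=24 ES=24 EE=24
B1X B2X SS=90 SE=55 ES=76 EE=39
B1X B2Y SS=68 SE=81 ES=61 EE=61
B1X B3X SS=67 SE=98 ES=81 EE=104
B1X B3Y SS=72 SE=95 ES=77 EE=108
B1Y B2X SS=66 SE=32 ES=100 EE=63
B1Y B2Y SS=44 SE=60 ES=83 EE=85
B1Y B3X SS=57 SE=81 ES=91 EE=120
B1Y B3Y SS=54 SE=84 ES=93 EE=118
B2X B2Y SS=27 SE=27 ES=27 EE=27
B2X B3X SS=80 SE=71 ES=71 EE=80
B2X B3Y SS=54 SE=93 ES=54 EE=93
B2Y B3X SS=54 SE=54 ES=93 EE=93
B2Y B3Y SS=31 SE=71 ES=71 EE=111
B3X B3Y SS=27 SE=27 ES=27 EE=27
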