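name,r,g,b,hex
White,255,255,255,#FFFFFF
Bright White,250,250,255,#FAFAFF
Pink,255,192,203,#FFC0CB
Red,255,0,0,#FF0000
Orange,255,165,0,#FFA500
Yellow,255,255,0,#FFFF00
Bright Yellow,255,234,0,#FFEA00
Green,0,128,0,#008000
Blue,0,0,255,#0000FF
Blue White,204,221,238,#CCDDEE
Blue Gray,102,153,204,#6699CC
Indigo,75,0,130,#4B0082
Violet,238,130,238,#EE82EE
Brown,165,42,42,#A52A2A
Light Brown,196,164,132,#C4A484
Gray Brown,139,125,107,#8B7D6B
Black,0,0,0,#000000
Non-pigmented,,,,
Hypopigmented,,,,
Pigmented,,,,
Dark,,,,
Uniform,,,,
Variable,,,,
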