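00000000000000000000000000000000000000000000000000
00000000000000000000000000000000000000000000000000
00000000000000000000000000000000000000000000000000
00000000000000000000000000000000000000000000000000
00000000000000000000000000000000000000000000000000
00000000000000000000000000000000000000000000000000
00000000000000000000000111000000000000000000000000
00000000000000000000000111000000000000000000000000
00000000000000000000000111000000000000000000000000
00000000000111111111111000100000000000000000000000
00000000001000000000000000010000000000000000000000
00000000001000000000000000001000000000000000000000
00000000001000000000000000000100000000000000000000
00000000001000000000000000000100000000000000000000
00000000001000000000000000000100000000000000000000
00000000001000000000000000000100000000000000000000
00000000001000000000000000000100000000000000000000
00000000001000000000000000000100000000000000000000
00000000001000000000000000000100000000000000000000
00000000001000000000000000000100000000000000000000
00000000001000000000000000000100000000000000000000
00000000001000000000000000000100000000000000000000
00000000001000000000000000000100000000000000000000
00000000001000000000000000000100000000000000000000
00000000001000000000000000000100000000000000000000
00000000001000000000000000000100000000000000000000
00000000001000000000000000000100000000000000000000
00000000001000000000000000000100000000000000000000
00000000001000000000000000000100000000000000000000
00000000001000000000000000000100000000000000000000
00000000001000000000000000000100000000000000000000
00000000001000000000000000000100000000000000000000
00000000001000000000000000000100000000000000000000
00000000001000000000000000000100000000000000000000
00000000001000000000000000000100000000000000000000
00000000001000000000000000000100000000000000000000
00000000001111111110000000000100000000000000000000
00000000000000000001000000000100000000000000000000
00000000000000000000100000001000000000000000000000
00000000000000000000010000010000000000000000000000
00000000000000000000001000100000000000000000000000
00000000000000000000000111000000000000000000000000
00000000000000000000000111000000000000000000000000
00000000000000000000000111000000000000000000000000
00000000000000000000000000000000000000000000000000
00000000000000000000000000000000000000000000000000
00000000000000000000000000000000000000000000000000
00000000000000000000000000000000000000000000000000
00000000000000000000000000000000000000000000000000
00000000000000000000000000000000000000000000000000
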