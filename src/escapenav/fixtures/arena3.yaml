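arena_id: 3
start: [42, 24]
goal: [7, 24]
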