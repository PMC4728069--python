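# Observed frequency bands (Hz) per species / call type, key = low,high.
# A band starting at 0 selects a low-pass post-filter; edit freely.

# New Zealand species, syllable-level call types
kiwi.male          = 500,8000
kiwi.female        = 500,6500
ruru.trill         = 500,8000
ruru.more          = 500,2000
ruru.pork          = 500,2000
kakapo.booming     = 0,800
kakapo.chinging    = 1000,12000

# whole-song bands
robin              = 1700,12500
tui                = 400,18000
kaka               = 700,15000
hihi               = 1000,21000
saddleback         = 800,22000
marsh_wren         = 500,15000
western_meadowlark = 650,12500
horned_lark        = 1100,18000
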