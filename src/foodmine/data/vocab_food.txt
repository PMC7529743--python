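garlic
cocoa
cacao
chocolate
allium
onion
clove
bulb
fruit
vegetable
bean
seed
legume
spice
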