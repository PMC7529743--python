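flavonoid
polyphenol
phenolic
alkaloid
sulfide
disulfide
trisulfide
amino acid
fatty acid
antioxidant
theobromine
caffeine
catechin
quercetin
anthocyanin
terpene
glucoside
sterol
tocopherol
carotenoid
organosulfur
methylxanthine
procyanidin
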