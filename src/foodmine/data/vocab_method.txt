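hplc
chromatography
gas chromatography
liquid chromatography
mass spectrometry
gc-ms
lc-ms
spectrophotometry
nmr
spectroscopy
titration
electrophoresis
quantification
quantitative analysis
colorimetric assay
icp-ms
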