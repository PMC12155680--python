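# Mini catalog of representative pan-assay interference (PAINS) motifs.
# Format: SMARTS<TAB>name. This is a 10-pattern test/demo catalog, not a
# replacement for the full published PAINS families; point the pipeline
# at a complete pattern file for production screens.
O=C1NC(=S)SC1	rhodanine
C=C1SC(=S)NC1=O	ene_rhodanine
c1cc(O)c(O)cc1	catechol
O=C1C=CC(=O)C=C1	para_quinone
cN=Nc	azo_aromatic
C=C1C(=O)NC(=O)NC1=O	alkylidene_barbiturate
c[N+](=O)[O-]	nitroaromatic
NC(=S)N	thiourea
C=NN=C	azine
[#6]=N[NH1]	hydrazone
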