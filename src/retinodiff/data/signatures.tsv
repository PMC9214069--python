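# Marker-wave gene sets for hESC-to-RPE differentiation (editable).
# Columns: signature_name <TAB> gene_symbol
pluripotency	POU5F1
pluripotency	LIN28A
pluripotency	SOX2
pluripotency	NANOG
pluripotency	SALL4
retinal_progenitor	RAX
retinal_progenitor	PAX6
retinal_progenitor	VSX2
retinal_progenitor	SIX6
retinal_progenitor	LHX2
rpe_early	MITF
rpe_early	TYRP1
rpe_early	PMEL
rpe_early	TMEFF2
rpe_mid	TYR
rpe_mid	RLBP1
rpe_late	RPE65
rpe_late	BEST1
rpe_late	RGR
rpe	MITF
rpe	TYRP1
rpe	PMEL
rpe	TMEFF2
rpe	TYR
rpe	RLBP1
rpe	RPE65
rpe	BEST1
rpe	RGR
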