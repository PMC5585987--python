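element_id	consensus	note
MBS	CAACTG	MYB binding site; drought responsiveness (synthetic consensus reconstruction)
ABRE	ACGTGGC	ABA-responsive element (synthetic consensus reconstruction)
HSE	AGAANNTTCT	heat-shock element (synthetic consensus reconstruction)
LTR	CCGAAA	low-temperature responsiveness (synthetic consensus reconstruction)
DRE	RCCGAC	dehydration / low-temperature / salt responsive element (synthetic consensus reconstruction)
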