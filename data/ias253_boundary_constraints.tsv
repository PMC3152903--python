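reaction_id	lb	ub	source
O2_bCyto	0	19.8	measured oxygen uptake of resting heart, umol/min/gDW
EX_O2_in	0	19.8	measured oxygen uptake of resting heart, umol/min/gDW
Glc_bCyto	0	0.9	measured glucose uptake of resting heart, umol/min/gDW
EX_Glc_in	0	0.9	measured glucose uptake of resting heart, umol/min/gDW
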