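# Fallback mapping from ether/hydroxy/glyco subclasses to the parent class
# whose internal standard is used for quantification.  Editable: rows here are
# only consulted when a species' annotated class has no standard of its own.
alias,parent
PC[O],PC
PC[P],PC
PC[O+P],PC
LPC[O],LPC
LPC[P],LPC
LPC[O+P],LPC
PE[O],PE
PE[P],PE
PE[O+P],PE
LPE[O],LPE
LPE[P],LPE
LPE[O+P],LPE
SM[d],SM
SM[t],SM
SPH[d],SPH
Cer[d],Cer
HexCer,GlcCer
HexCer[d],GlcCer
Hex2Cer,LacCer
Hex2Cer[d],LacCer
GM3,LacCer
TAG[O],TAG
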