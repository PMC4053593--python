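treatment,compartment,qualifier
RC,air,primary
RC,water,indirect
RC,soil,indirect
LF,water,primary
LF,soil,indirect
IN,air,primary
IN,soil,residual_stream
BT,soil,primary
BT,water,indirect
UOL,soil,primary
UOL,water,indirect
COLLECTION,air,primary
COLLECTION,soil,indirect
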