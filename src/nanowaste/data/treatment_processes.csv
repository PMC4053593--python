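treatment,process
LF,reduction
LF,dissolution_precipitation
LF,adsorption_desorption
LF,oxidation
IN,combustion
BT,biotransformation_biodegradation
UOL,biotransformation_biodegradation
RC,abrasion_mechanical_erosion
COLLECTION,abrasion_mechanical_erosion
COLLECTION,photochemical_transformation
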