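nanoproduct,enm_type,matrix_material,matrix_state,nanostructure,waste_fraction,treatments,secondary_stream
Nanosilver textile,Ag,Cotton textile,solid,surface_bound,Textiles,RE|RC|IN|LF,false
NanoTiO2 sunscreen,TiO2,Lotion cream,liquid,suspended_in_liquid,Residual,IN|LF,false
NanoTiO2 sunscreen,TiO2,Plastic flacon,solid,surface_bound,Residual,IN|LF,false
CNT tennis racquet,CNT,Carbon fibre,solid,suspended_in_solid,Residual or bulky waste,IN|LF,false
NanoZnO in food additives,ZnO,Organic matter,solid,suspended_in_solid,Organic waste,BT|IN|LF,false
NanoTiO2 wall paint,TiO2,Paint (wet),liquid,suspended_in_liquid,Construction & demolition (C&D) waste,RE|LF,false
NanoTiO2 wall paint,TiO2,Paint (dried),solid,suspended_in_solid,Construction & demolition (C&D) waste,RE|LF,false
Nano-coated glass,TiO2,Glass,solid,surface_bound,Glass,RE,false
Li-ion batteries,CNT,Mix of organic carbonates and lithium salts,solid,bulk_nanostructured,Batteries,RE|IN,false
Circuit printboard,Various,Metal and plastic,solid,surface_bound,Waste electrical and electronic equipment (WEEE),RE,false
Circuit printboard,Various,Metal and plastic,solid,suspended_in_solid,Waste electrical and electronic equipment (WEEE),RE,false
Circuit printboard,Various,Metal and plastic,solid,bulk_nanostructured,Waste electrical and electronic equipment (WEEE),RE,false
WWTP sludge with NanoZnO,ZnO,Organic matter,solid,suspended_in_solid,WWTP sludge,BT|UOL|IN,true
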