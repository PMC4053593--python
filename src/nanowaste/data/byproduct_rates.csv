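waste_name,unit,rate_low,rate_high,enm_type,source,comment
Ag+ in H2O solution,g/g,0.43,0.43,Ag,Tolaymat et al. 2010,Probably discharged as wastewater
Trimethyl aluminium Al2(CH3)6,g/g,0.98,0.98,Al2O3,Yuan and Dornfeld 2010,Atomic layer deposition (ALD) process
Thiol solvent,L/g,15,15,Au,Dahl et al. 2007,Purification process
Carbon soot,g/g,2,9,CNF,Khanna et al. 2008,Vapour grown carbon nanofibers (VGCNFs)
Carbon soot,g/g,2,33,CNT-CNF,Zhang et al. 2011,Review of various synthesis methods
Carbon soot,g/g,0.9,0.9,Fullerene,Royal Commission on Environmental Pollution 2008,Sent to landfill
Carbon soot,g/g,7.22,25.6,Fullerene,Anctil et al. 2011,Production: pyrolysis (toluene/tetralin) and plasma RF/Arc (graphite)
Carbon soot,g/g,9,9,SWCNT,Seager et al. 2008,SWCNT synthesis
Carbon soot,g/g,21.2,21.2,SWCNT,Isaacs et al. 2010,Arc ablation (ARC) synthesis
Carbon soot,g/g,31.9,31.9,SWCNT,Isaacs et al. 2010,Chemical vapour deposition (CVD) synthesis
Carbon soot,g/g,1250,1250,SWCNT,Isaacs et al. 2010,High pressure carbon monoxide (HiPco) synthesis
PTFE scrap membrane,g/g,11.91,11.91,SWCNT,Healy et al. 2008,Purification after ARC synthesis
PTFE scrap membrane,g/g,6.17,6.17,SWCNT,Healy et al. 2008,Purification after CVD synthesis
PTFE scrap membrane,g/g,5.73,5.73,SWCNT,Healy et al. 2008,Purification after HiPco synthesis
Mix of ilmenite iron powder and HCl,g/g,1.33,1.33,TiO2,Grubb and Bakshi 2011,Altair(nano) hydrochloride process
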