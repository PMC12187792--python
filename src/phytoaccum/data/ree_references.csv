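reference,element,value_mg_kg,source
PAAS-TM1985,La,38.2,"Taylor & McLennan (1985), The Continental Crust: its Composition and Evolution"
PAAS-TM1985,Ce,79.6,"Taylor & McLennan (1985), The Continental Crust: its Composition and Evolution"
PAAS-TM1985,Pr,8.83,"Taylor & McLennan (1985), The Continental Crust: its Composition and Evolution"
PAAS-TM1985,Nd,33.9,"Taylor & McLennan (1985), The Continental Crust: its Composition and Evolution"
PAAS-TM1985,Y,27.0,"Taylor & McLennan (1985), The Continental Crust: its Composition and Evolution"
PAAS-P2012,La,44.56,"Pourmand, Dauphas & Ireland (2012), Chem. Geol. 291, 38-54"
PAAS-P2012,Ce,88.25,"Pourmand, Dauphas & Ireland (2012), Chem. Geol. 291, 38-54"
PAAS-P2012,Pr,10.15,"Pourmand, Dauphas & Ireland (2012), Chem. Geol. 291, 38-54"
PAAS-P2012,Nd,37.32,"Pourmand, Dauphas & Ireland (2012), Chem. Geol. 291, 38-54"
PAAS-P2012,Y,27.31,"Pourmand, Dauphas & Ireland (2012), Chem. Geol. 291, 38-54"
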