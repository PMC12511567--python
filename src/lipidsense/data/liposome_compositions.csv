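# Built-in liposome compositions (mol%), one row per (mixture, species).
# Labels name the phospholipid mix by its saturated-acyl-chain content;
# "+cholesterol" variants keep the parent label as metadata.
# The "35% SFA" mix is assigned POPC 70 / DOPC 10 / DOPE 20, the only
# PC/PE split at the stated PC:PE ratio consistent with its label.
label,species,mol_percent
33% SFA (ER-like),POPC,60
33% SFA (ER-like),DOPE,20
33% SFA (ER-like),DOPS,10
33% SFA (ER-like),cholesterol,10
10% SFA,DOPC,60
10% SFA,POPC,20
10% SFA,DOPE,20
35% SFA,POPC,70
35% SFA,DOPC,10
35% SFA,DOPE,20
40% SFA,POPC,80
40% SFA,DOPE,20
50% SFA,POPC,80
50% SFA,POPE,20
60% SFA,POPC,60
60% SFA,DPPC,20
60% SFA,POPE,20
35% SFA +cholesterol,POPC,66.7
35% SFA +cholesterol,DOPC,6.7
35% SFA +cholesterol,DOPE,16.7
35% SFA +cholesterol,cholesterol,10
60% SFA +cholesterol,POPC,56.7
60% SFA +cholesterol,DPPC,16.7
60% SFA +cholesterol,POPE,16.7
60% SFA +cholesterol,cholesterol,10
10% SFA (PC only),DOPC,80
10% SFA (PC only),POPC,20
60% SFA (PC only),POPC,80
60% SFA (PC only),DPPC,20
10% SFA (16 carbons),16:1 PC,60
10% SFA (16 carbons),POPC,20
10% SFA (16 carbons),16:1 PE,20
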