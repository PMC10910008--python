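class,antibiotic,standardized_cost
Cephalosporins 1st/2nd generation,cephalexin,0.76
Cephalosporins 3rd/4th generation,cefovecin,2.53
Lincosamides,clindamycin,0.63
Macrolides,azithromycin,0.73
Macrolides,erythromycin,0.34
Nitroimidazoles,metronidazole,1.34
Penicillins,amoxicillin,0.15
Penicillins,co-amoxiclav,1.00
Fluoroquinolones,enrofloxacin,0.72
Fluoroquinolones,marbofloxacin,0.81
Fluoroquinolones,pradofloxacin,0.89
Sulfonamides,trimethoprim-sulfonamide,0.14
Tetracyclines,doxycycline,1.67
Tetracyclines,oxytetracycline,0.38
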