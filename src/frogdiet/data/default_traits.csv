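taxon,hardness,motility,habitat_origin,vertebrate_class
Acari,medium,medium,terrestrial,none
Agamidae,medium,evasive,terrestrial,Reptilia
Amphipoda,medium,medium,aquatic,none
Anura,soft,evasive,terrestrial,Amphibia
Aranae,medium,evasive,terrestrial,none
Arthropoda,medium,medium,terrestrial,none
Blattaria,medium,evasive,terrestrial,none
Chilopoda,medium,evasive,terrestrial,none
Coleoptera,hard,evasive,terrestrial,none
Brachyura,hard,medium,aquatic,none
Dermaptera,medium,medium,terrestrial,none
Diplopoda,hard,sedentary,terrestrial,none
Diptera,soft,evasive,volant,none
Formicidae,hard,medium,terrestrial,none
Gastropoda,soft,sedentary,terrestrial,none
Geckonnidae,medium,evasive,terrestrial,Reptilia
Hemiptera,medium,evasive,terrestrial,none
Hymenoptera,medium,evasive,volant,none
Insecta,medium,medium,terrestrial,none
Isoptera,soft,sedentary,terrestrial,none
Lacertidae,medium,evasive,terrestrial,Reptilia
Lepidoptera,soft,evasive,volant,none
Leplarva,soft,sedentary,terrestrial,none
Mantodea,medium,evasive,terrestrial,none
Odonata,medium,evasive,volant,none
Oligochaeta,soft,sedentary,terrestrial,none
Opilionida,medium,medium,terrestrial,none
Orthoptera,medium,evasive,terrestrial,none
Rodentia,medium,evasive,terrestrial,Mammalia
Scincidae,medium,evasive,terrestrial,Reptilia
Serpentes,medium,evasive,terrestrial,Reptilia
Siphonaptera,hard,evasive,terrestrial,none
Gastropoda_2,soft,sedentary,aquatic,none
Unidentified,unknown,unknown,unknown,none
Zygentoma,soft,evasive,terrestrial,none
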