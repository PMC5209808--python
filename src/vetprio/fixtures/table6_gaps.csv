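category,disease_id,disease_name,diagnostics,vaccines,pharmaceuticals
epizootic,peste_des_petits_ruminants,Peste des petits ruminants,-5,-10,20
epizootic,african_swine_fever,African swine fever,-50,40,40
epizootic,rift_valley_fever,Rift valley fever,29,18,40
epizootic,foot_and_mouth_disease,Foot and mouth disease,-32,-20,40
epizootic,african_horse_sickness,African horse sickness,-18,20,10
epizootic,contagious_bovine_pleuropneumonia,Contagious bovine pleuro pneumonia,9,30,25
epizootic,classical_swine_fever,Classical swine fever,-23,-50,40
epizootic,lumpy_skin_disease,Lumpy skin disease,27,-5,40
epizootic,bluetongue,Bluetongue,-27,-15,40
epizootic,orthopox,Orthopox,18,40,15
food_producing_complex,poultry_coccidiosis,Coccidiosis,9,5,-35
food_producing_complex,paratuberculosis,Paratuberculosis,0,0,40
food_producing_complex,liver_fluke,Liver fluke,-9,40,-25
food_producing_complex,nematodes,Nematodes,-5,40,-65
food_producing_complex,bovine_viral_diarrhoea_virus,Bovine viral diarrhoea virus,-27,-10,40
food_producing_complex,porcine_circo_virus_type_2,Porcine circo virus type 2,20,-40,40
food_producing_complex,small_ruminant_mastitis,Small ruminant mastitis,-23,-5,-50
food_producing_complex,varroa_mite,Varroa mite,40,40,-10
food_producing_complex,staphylococcus_aureus_mastitis,Staphylococcus aureus mastitis,14,0,-30
food_producing_complex,theileria,Theileria,27,40,-30
zoonotic,nipah_virus,Nipah virus,0,0,0
zoonotic,bovine_tuberculosis,Bovine tuberculosis,-18,10,40
zoonotic,non_tse_tse_transmitted_animal_trypanosomiasis,Non tse-tse transmitted trypanosomiasis,32,40,15
zoonotic,cryptosporidiosis,Cryptosporidiosis,0,40,-45
zoonotic,salmonellosis,Salmonellosis,-23,-30,-35
zoonotic,leishmaniosis,Leishmaniosis,-14,35,-20
zoonotic,brucellosis,Brucellosis,-5,20,40
zoonotic,leptospirosis,Leptospirosis,-5,5,-60
zoonotic,hepatitis_e_virus,Hepatitis E virus,-32,40,40
zoonotic,anthrax,Anthrax,36,5,-45
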