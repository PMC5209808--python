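category,position,disease_id,disease_name,score
epizootic,1,peste_des_petits_ruminants,Peste des petits ruminants,385
epizootic,2,african_swine_fever,African swine fever,373
epizootic,3,rift_valley_fever,Rift valley fever,365
epizootic,4,foot_and_mouth_disease,Foot and mouth disease,310
epizootic,5,african_horse_sickness,African horse sickness,294
epizootic,6,contagious_bovine_pleuropneumonia,Contagious bovine pleuropneumonia,269
epizootic,7,classical_swine_fever,Classical swine fever,247
epizootic,8,lumpy_skin_disease,Lumpy skin disease,244
epizootic,9,bluetongue,Bluetongue,241
epizootic,10,orthopox,Orthopox,237
epizootic,11,sheep_and_goat_pox_virus,Sheep and goat pox virus,218
epizootic,12,avian_influenza,Avian Influenza,209
epizootic,13,parapox,Parapox,152
epizootic,14,swine_vesicular_disease,Swine vesicular disease,118
epizootic,15,west_nile_virus,West Nile Virus,118
epizootic,16,bovine_herpes_virus_type_1,Bovine herpes virus type 1,107
epizootic,17,porcine_reproductive_and_respiratory_syndrome_virus,Porcine reproductive and respiratory syndrome virus,107
food_producing_complex,1,poultry_coccidiosis,Poultry coccidiosis,226
food_producing_complex,2,paratuberculosis,Paratuberculosis,223
food_producing_complex,3,liver_fluke,Liver fluke,202
food_producing_complex,4,nematodes,Nematodes,193
food_producing_complex,5,porcine_circo_virus_type_2,Porcine circo virus type 2,183
food_producing_complex,6,bovine_viral_diarrhoea_virus,Bovine viral diarrhoea virus,183
food_producing_complex,7,small_ruminant_mastitis,Small ruminant mastitis,179
food_producing_complex,8,varroa_mite,Varroa mite,177
food_producing_complex,9,staphylococcus_aureus_mastitis,Staphylococcus aureus mastitis,175
food_producing_complex,10,theileria,Theileria,174
food_producing_complex,11,mycoplasma_bovis,Mycoplasma bovis,173
food_producing_complex,12,swine_influenza_virus,Swine influenza virus,162
food_producing_complex,13,swine_actinobacillus_pleuropneumonia,Swine Actinobacillus pleuropneumonia,159
food_producing_complex,14,bovine_respiratory_syncytial_virus,Bovine respiratory syncytial virus,153
food_producing_complex,15,swine_mycoplasma,Swine mycoplasma,143
food_producing_complex,16,environmental_streptococcal_mastitis,Environmental/Streptococcal mastitis,83
zoonotic,1,nipah_virus,Nipah virus,464
zoonotic,2,bovine_tuberculosis,Bovine tuberculosis,359
zoonotic,3,non_tse_tse_transmitted_animal_trypanosomiasis,Non tse-tse transmitted animal trypanosomiasis,296
zoonotic,4,cryptosporidiosis,Cryptosporidiosis,291
zoonotic,5,salmonellosis,Salmonellosis,282
zoonotic,6,leishmaniosis,Leishmaniosis,262
zoonotic,7,brucellosis,Brucellosis,254
zoonotic,8,leptospirosis,Leptospirosis,250
zoonotic,9,hepatitis_e_virus,Hepatitis E virus,237
zoonotic,10,anthrax,Anthrax,220
zoonotic,11,campylobacter,Campylobacter,219
zoonotic,12,q_fever,Q-fever,214
zoonotic,13,rabies,Rabies,212
zoonotic,14,verocytotoxigenic_escherichia_coli,Verocytotoxigenic Escherichia coli,209
zoonotic,15,chlamydophila_abortus,Chlamydophila abortus,197
zoonotic,16,bovine_spongiform_encephalopathy,Bovine spongiform encephalopathy,180
zoonotic,17,echinococcosis,Echinococcosis,167
zoonotic,18,congo_crimean_haemorrhagic_fever,Congo crimean haemorrhagic fever,162
zoonotic,19,cysticercosis,Cysticercosis,130
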