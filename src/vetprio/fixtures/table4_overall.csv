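disease_id,disease_name,category,overall_score
nipah_virus,Nipah virus,zoonotic,464
peste_des_petits_ruminants,Peste des petits ruminants,epizootic,385
african_swine_fever,African swine fever,epizootic,373
rift_valley_fever,Rift valley fever,epizootic,365
bovine_tuberculosis,Bovine tuberculosis,zoonotic,359
foot_and_mouth_disease,Foot and mouth disease,epizootic,310
non_tse_tse_transmitted_animal_trypanosomiasis,Non tse-tse transmitted animal trypanosomiasis,zoonotic,296
african_horse_sickness,African horse sickness,epizootic,294
cryptosporidiosis,Cryptosporidiosis,zoonotic,291
salmonellosis,Salmonellosis,zoonotic,282
contagious_bovine_pleuropneumonia,Contagious bovine pleuropneumonia,epizootic,269
leishmaniosis,Leishmaniosis,zoonotic,262
brucellosis,Brucellosis,zoonotic,254
leptospirosis,Leptospirosis,zoonotic,250
classical_swine_fever,Classical swine fever,epizootic,247
lumpy_skin_disease,Lumpy skin disease,epizootic,244
bluetongue,Bluetongue,epizootic,241
orthopox,Orthopox,epizootic,237
hepatitis_e_virus,Hepatitis E virus,zoonotic,237
poultry_coccidiosis,Poultry coccidiosis,food_producing_complex,226
paratuberculosis,Paratuberculosis,food_producing_complex,223
anthrax,Anthrax,zoonotic,220
campylobacter,Campylobacter,zoonotic,219
sheep_and_goat_pox_virus,Sheep and goat pox virus,epizootic,218
q_fever,Q-fever,zoonotic,214
rabies,Rabies,zoonotic,212
avian_influenza,Avian Influenza,epizootic,209
verocytotoxigenic_escherichia_coli,Verocytotoxigenic Escherichia coli,zoonotic,209
liver_fluke,Liver fluke,food_producing_complex,202
chlamydophila_abortus,Chlamydophila abortus,zoonotic,197
nematodes,Nematodes,food_producing_complex,193
porcine_circo_virus_type_2,Porcine circo virus type 2,food_producing_complex,183
bovine_viral_diarrhoea_virus,Bovine viral diarrhoea virus,food_producing_complex,183
bovine_spongiform_encephalopathy,Bovine spongiform encephalopathy,zoonotic,180
small_ruminant_mastitis,Small ruminant mastitis,food_producing_complex,179
varroa_mite,Varroa mite,food_producing_complex,177
staphylococcus_aureus_mastitis,Staphylococcus aureus mastitis,food_producing_complex,175
theileria,Theileria,food_producing_complex,174
mycoplasma_bovis,Mycoplasma bovis,food_producing_complex,173
echinococcosis,Echinococcosis,zoonotic,167
swine_influenza_virus,Swine influenza virus,food_producing_complex,162
congo_crimean_haemorrhagic_fever,Congo crimean haemorrhagic fever,zoonotic,162
swine_actinobacillus_pleuropneumonia,Swine Actinobacillus pleuropneumonia,food_producing_complex,159
bovine_respiratory_syncytial_virus,Bovine respiratory syncytial virus,food_producing_complex,153
parapox,Parapox,epizootic,152
swine_mycoplasma,Swine mycoplasma,food_producing_complex,143
cysticercosis,Cysticercosis,zoonotic,130
swine_vesicular_disease,Swine vesicular disease,epizootic,118
west_nile_virus,West Nile Virus,epizootic,118
bovine_herpes_virus_type_1,Bovine herpes virus type 1,epizootic,107
porcine_reproductive_and_respiratory_syndrome_virus,Porcine reproductive and respiratory syndrome virus,epizootic,107
environmental_streptococcal_mastitis,Environmental/Streptococcal mastitis,food_producing_complex,83
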