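category	n_sequences	n_projects
activated_carbon	44	1
activated_sludge	7383	78
air	300	3
algae	308	4
anaerobic_digester	500	5
annelid	1038	13
ant	300	3
aquatic	2667	29
aquifer	1900	19
bat	143	2
beach_sand	100	1
biofilm	300	3
biofilter	100	1
biogas_fermenter	600	6
bioreactor	2923	32
bioreactor_sludge	200	2
biosolids	200	2
bird	100	1
bovine	200	2
bovine_gut	700	7
cave	100	1
chicken_gut	731	9
compost	500	5
coral	1100	11
crab	100	1
crustacean	100	1
endophyte	30	1
epibiont	100	1
estuary	200	2
feces	1306	14
fermentation	300	3
fish_gut	25	1
food	604	7
food_fermentation	300	3
food_production	100	1
fossil	200	2
freshwater	43216	437
freshwater_sediment	13744	239
fungus	3737	38
glacier	500	5
groundwater	9540	97
gut	3167	36
halite	14	1
hot_springs	1056	12
human_bile	111	2
human_blood	1	1
human_eye	131	2
human	1815	25
human_gut	7502	80
human_lung	291	3
human_oral	500	5
human_reproductive_system	100	1
human_skin	400	4
hydrocarbon	33	1
hydrothermal_vent	4016	44
hypersaline_lake	900	9
hypolithon	113	2
indoor	100	1
insect	241	4
insect_gut	200	2
invertebrate	300	3
lake_water	5700	57
landfill	400	4
leaf	500	5
lichen	500	5
marine	45298	461
marine_sediment	3281	35
microbial_fuel_cell	100	1
microbial_mat	1561	17
mine_drainage	200	2
mine_tailings	200	2
mixed_culture	100	1
money	200	2
mosquito	180	2
moss	600	6
mouse_gut	1194	18
oil_field	3	1
oral	66	1
oyster	100	1
paper_pulp	100	1
parasite	26	1
peat	7683	77
permafrost	1449	16
phyllosphere	12100	121
pig_gut	576	6
plant	4579	53
plastic	6	3
pollen	200	2
rat_gut	100	1
rhizosphere	21152	213
rice_paddy	3100	31
rock	148	2
rock_porewater	100	1
root_associated_fungus	100	4
root	400	1
salt_lake	1900	19
salt_marsh	5400	54
sea_squirt	400	4
seawater	2977	30
sediment	6431	66
skin	100	1
sludge	100	1
soil	90158	984
sponge	300	3
stromatolite	100	1
subsurface	3020	32
surface	100	1
symbiont	69	1
termite_gut	2919	31
terrestrial	2134	22
tick	100	1
urban	6	1
viral	600	6
wastewater	3228	35
wetland	11900	119
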