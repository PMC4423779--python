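taxon_group,common_name,latin_name,species_id,ev_dry_random,ev_dry_trail,ev_wet_random,ev_wet_trail,rai_dry_random,rai_dry_trail,rai_wet_random,rai_wet_trail
Primata,Vervet monkey,Cercopithecus pygerythrus,vervet_monkey,9,14,8,17,0.32,0.50,0.34,0.66
Primata,Yellow baboon,Papio cynocephalus,yellow_baboon,95,120,67,102,3.34,4.26,2.85,3.99
Carnivora,Black-backed jackal,Canis mesomelas,black_backed_jackal,44,133,30,65,1.55,4.72,1.28,2.54
Carnivora,Bat-eared fox,Octocyon megalotis,bat_eared_fox,44,28,26,15,1.55,0.99,1.11,0.59
Carnivora,African wild dog,Lycaon pictus,african_wild_dog,0,0,0,2,0.00,0.00,0.00,0.08
Carnivora,Honey badger,Mellivora capensis,honey_badger,3,9,5,4,0.11,0.32,0.21,0.16
Carnivora,Banded mongoose,Mungos mungo,banded_mongoose,3,19,4,7,0.11,0.67,0.17,0.27
Carnivora,Bushy-tailed mongoose,Bdeogale crassicauda,bushy_tailed_mongoose,2,2,0,1,0.07,0.07,0.00,0.04
Carnivora,Slender mongoose,Herpestes sanguinea,slender_mongoose,9,15,2,7,0.32,0.53,0.09,0.27
Carnivora,White-tailed mongoose,Ichneumia albicauda,white_tailed_mongoose,35,59,11,26,1.23,2.09,0.47,1.02
Carnivora,Spotted hyena,Crocuta crocuta,spotted_hyena,99,211,62,165,3.48,7.48,2.64,6.45
Carnivora,Aardwolf,Proteles cristata,aardwolf,19,78,28,48,0.67,2.77,1.19,1.88
Carnivora,Common genet,Genetta genetta,common_genet,18,60,15,26,0.63,2.13,0.64,1.02
Carnivora,Blotched genet,Genetta tigrina,blotched_genet,1,0,0,4,0.04,0.00,0.00,0.16
Carnivora,African civet,Civettictis civetta,african_civet,15,35,4,11,0.53,1.24,0.17,0.43
Carnivora,Wild cat,Felis sylvestris,wild_cat,2,24,6,2,0.07,0.85,0.26,0.08
Carnivora,Serval,Felis serval,serval,4,21,17,18,0.14,0.74,0.72,0.70
Carnivora,Caracal,Felis caracal,caracal,1,1,0,2,0.04,0.04,0.00,0.08
Carnivora,Cheetah,Acinonyx jubatus,cheetah,0,2,2,1,0.00,0.07,0.09,0.04
Carnivora,Leopard,Panthera pardus,leopard,12,54,10,36,0.42,1.91,0.43,1.41
Carnivora,Lion,Panthera leo,lion,12,44,8,40,0.42,1.56,0.34,1.56
Pholidota,Ground pangolin,Smutsia temminckii,ground_pangolin,1,0,1,0,0.04,0.00,0.04,0.00
Rodentia,Crested porcupine,Hystrix cristata,crested_porcupine,1,23,3,20,0.04,0.82,0.13,0.78
Ungulata,Aardvark,Orycteropus afer,aardvark,13,13,5,13,0.46,0.46,0.21,0.51
Ungulata,African elephant,Loxodonta africana,african_elephant,354,428,1146,1671,12.45,15.18,48.83,65.35
Ungulata,Common zebra,Equus quagga,common_zebra,162,172,144,168,5.70,6.10,6.14,6.57
Ungulata,Hippopotamus,Hippopotamus amphibious,hippopotamus,42,123,66,201,1.48,4.36,2.81,7.86
Ungulata,Bush pig,Potamochoerus larvatus,bush_pig,1,3,0,4,0.04,0.11,0.00,0.16
Ungulata,Warthog,Phacochoerus africanus,warthog,34,36,68,84,1.20,1.28,2.90,3.29
Ungulata,Giraffe,Giraffa camelopardalis,giraffe,229,390,110,165,8.05,13.83,4.69,6.45
Ungulata,African buffalo,Syncerus caffer,african_buffalo,10,12,0,0,0.35,0.43,0.00,0.00
Ungulata,Bushbuck,Tragelaphus scriptus,bushbuck,6,5,1,1,0.21,0.18,0.04,0.04
Ungulata,Lesser kudu,Tragelaphus imberbis,lesser_kudu,20,25,44,28,0.70,0.89,1.87,1.10
Ungulata,Greater kudu,Tragelaphus strepsiceros,greater_kudu,170,215,88,112,5.98,7.62,3.75,4.38
Ungulata,Eland,Taurotragus oryx,eland,4,3,5,9,0.14,0.11,0.21,0.35
Ungulata,Bush duiker,Sylvicapra grimmia,bush_duiker,60,41,14,36,2.11,1.45,0.60,1.41
Ungulata,Klipspringer,Oreotragus oreotragus,klipspringer,0,2,0,1,0.00,0.07,0.00,0.04
Ungulata,Kirk's dikdik,Madoqua kirkii,kirks_dikdik,52,139,69,146,1.83,4.93,2.94,5.71
Ungulata,Grant's gazelle,Gazella granti,grants_gazelle,1,1,5,4,0.04,0.04,0.21,0.16
Ungulata,Impala,Aepyceros melampus,impala,1173,1929,996,1103,41.26,68.40,42.44,43.14
Ungulata,Waterbuck,Kobus ellipsiprymnus,waterbuck,22,23,3,6,0.77,0.82,0.13,0.23
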