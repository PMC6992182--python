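scientific_name,common_name,trophic_level,trophic_level_sd,lipid_content,length,length_sd,weight,weight_sd,n_individuals
Odontamblyopus rubicundus,Rubicundus eelgoby,3.9,0.5,1.38,18.1,1.9,24.1,6.4,10
Sillago sihama,Silver sillago,3.3,0.1,0.51,18.2,1.3,37.5,5.3,10
Selaroidea leptolepis,Yellow stripe trevally,3.8,0.2,2.10,12.0,2.1,25.4,3.8,10
Arius sinensis,Chinese sea catfish,3.9,0.7,2.70,22.9,2.7,104.0,19.2,10
Collichthys lucidus,Big head croaker,3.6,0.6,5.50,9.7,1.3,22.5,4.2,10
Ilisha elongata,Chinese herring,3.8,0.6,4.84,28.6,4.6,304.5,24.1,10
Thryssa kammalensis,Kammal thryssa,3.4,0.4,7.35,10.4,1.9,19.5,4.3,10
Thryssa dussumieri,Dussumier's thryssa,2.8,0.2,7.20,8.4,1.4,17.1,3.3,10
Larimichthys polyactis,Yellow croaker,3.7,0.4,3.08,13.5,1.8,70.1,5.9,10
Trichiurus lepturus,Hairtail,4.4,0.4,6.57,51.5,2.2,78.7,8.2,10
Pampus argenteus,Silver pomfret,3.3,0.1,6.60,20.5,2.6,168.8,6.6,10
Coilia mystus,Anchovies,3.2,0.4,6.28,17.1,2.0,16.1,2.2,10
Cynoglossus lida,Roughscale tonguesole,3.2,0.1,2.17,18.7,3.5,93.6,5.3,10
Harpadon nehereus,Bombay duck,4.2,0.7,1.41,21.8,2.9,96.2,4.2,10
Johnius belangerii,Belanger's croaker,3.3,0.3,6.35,13.9,0.8,48.8,3.8,10
Nemipterus virgatus,Golden threadfin bream,4.0,0.6,2.66,18.8,0.7,76.1,8.7,10
Mugil cephalus,Flathead mullet,2.5,0.2,4.77,17.2,0.4,52.4,3.3,10
Siganus fuscessens,Dusky rabbitfish,2.0,0.1,4.71,12.6,0.5,37.1,5.6,10
Branchiostegus albus,Horsehead tilefish,3.4,0.5,2.31,22.4,3.2,231.5,6.5,10
Leiognathus brevirostris,Shortnose ponyfish,3.0,0.3,6.00,12.5,1.3,27.7,1.7,10
Trypauchen vagina,Burrowing goby,3.5,0.5,3.22,13.8,2.2,12.5,2.4,10
Lateolabrax japonicus,Sea perch,3.1,0.3,1.60,29.5,2.1,228.2,26.4,10
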