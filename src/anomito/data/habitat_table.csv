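infraorder,superfamily,family,subfamily,species,accession,cr_length,location,at_percent,repeat_summary,dg_low,dg_high,depth_min_m,depth_max_m,terrestrial,vent,climate
Anomura,Paguroidea,Lithodidae,Hapalogastrinae,Hapalogaster dentata,OR523818,1313,between trnP and trnY,71.60,3.6 x 47 bp,-396.1,-395.1,0,10,False,False,Temperate
Anomura,Paguroidea,Lithodidae,Hapalogastrinae,Oedignathus inermis,OR523819,1300,between trnP and trnY,74.10,3.5 x 47 bp,-416.7,-415.4,0,45,False,False,Temperate
Anomura,Paguroidea,Lithodidae,Lithodinae,Paralithodes platypus,KY885248,1422,,75.10,"11.9 x 10 bp; 7.4 x 20 bp; 2.1 x 48 bp; 3.4 x 48 bp",-267.9,-267.1,10,180,False,False,Cold
Anomura,Paguroidea,Lithodidae,Lithodinae,Paralithodes camtschaticus,JX944381,1428,,77.90,"6.6 x 10 bp; 11.2 x 12 bp; 3.4 x 48 bp",-192.6,-192.1,10,200,False,False,Cold
Anomura,Paguroidea,Lithodidae,Lithodinae,Paralithodes brevipes,AB735677,979,,72.20,3.5 x 48 bp,-130.2,-129.2,10,280,False,False,Cold
Anomura,Paguroidea,Lithodidae,Lithodinae,Lithodes nintokuae,NC024202,275,between trnS2 and trnP,86.00,"3.1 x 51 bp; 2.1 x 76 bp; 6.2 x 25 bp",-19.7,-17.8,450,1070,False,False,Cold
Anomura,Paguroidea,Coenobitidae,,Birgus latro,KY352241,1381,between rrnS and trnS1,61.50,No Repeat,-297.1,-295.8,,,True,False,Tropic and subtropical
Anomura,Paguroidea,Coenobitidae,,Coenobita brevimanus,MK310257,1377,between rrnS and trnS2,62.10,No Repeat,-321.5,-320.6,,,True,False,Tropic and subtropical
Anomura,Paguroidea,Coenobitidae,,Coenobita clypeatus,ON203128,1390,between rrnS and trnS2,65.00,No Repeat,-244.8,-243.8,,,True,False,Tropic and subtropical
Anomura,Paguroidea,Coenobitidae,,Coenobita perlatus,KY352234,1356,between rrnS and trnS1,68.10,2.0 x 24 bp,-271.7,-270.7,,,True,False,Tropic and subtropical
Anomura,Paguroidea,Coenobitidae,,Coenobita rugosus,KY352235,1366,between rrnS and trnS1,65.60,2.2 x 18 bp,-264.9,-263.8,,,True,False,Tropic and subtropical
Anomura,Paguroidea,Coenobitidae,,Coenobita variabilis,KY352236,1371,between rrnS and trnS1,65.90,No Repeat,-254.8,-254.0,,,True,False,Tropic and subtropical
Anomura,Paguroidea,Diogenidae,,Clibanarius infraspinatus,NC025776,1500,,69.40,No Repeat,-179.1,-178.3,0,1,False,False,
Anomura,Paguroidea,Diogenidae,,Dardanus aspersus,MW715812,1461,between rrnS and trnS2,63.90,No Repeat,-784.3,-781.8,20,60,False,False,
Anomura,Paguroidea,Diogenidae,,Dardanus arrosor,MW147148,1496,between rrnS and trnS2,62.40,No Repeat,-796.4,-793.2,5,750,False,False,
Anomura,Paguroidea,Paguridae,,Pagurus rathbuni,OR523820,1124,between trnP and trnY,70.00,3.6 x 47 bp,-322.5,-321.0,60,590,False,False,Cold
Anomura,Paguroidea,Paguridae,,Pagurus gracilipes,LC222534,1120,between trnP and trnY,73.00,2.0 x 21 bp,-180.5,-179.5,0,60,False,False,Temperate
Anomura,Paguroidea,Paguridae,,Pagurus nigrofascia,MH756635,106,,75.50,No Repeat,-6.6,-6.0,0,5,False,False,Temperate
Anomura,Paguroidea,Paguridae,,Pagurus lanuginosus,LC222527,122,,86.00,4.2 x 10 bp,-5.0,6.6,0,5,False,False,Temperate
Anomura,Paguroidea,Paguridae,,Pagurus maculosus,LC222526,150,,80.70,No Repeat,-11.4,8.3,0,5,False,False,Temperate
Anomura,Paguroidea,Paguridae,,Pagurus japonicus,LC222532,484,,78.90,No Repeat,-49.8,-48.2,5,300,False,False,Temperate
Anomura,Paguroidea,Paguridae,,Pagurus longicarpus,AF150756,530,,65.30,3.2 x 45 bp,-80.6,-79.3,0,200,False,False,Temperate and subtropical
Anomura,Paguroidea,Paguridae,,Pagurus minutus,LC222533,Too compact,,,,,,0,2,False,False,Temperate
Anomura,Paguroidea,Paguridae,,Pagurus filholi,LC222528,63,between rrnL and trnV,76.20,No Repeat,-2.9,4,0,2,False,False,Temperate
Anomura,Paguroidea,Pylochelidae,,Pylocheles mortensenii,KY352242,Too compact,,,,,,100,627,False,False,Tropic
Anomura,Hippoidea,Albuneidae,,Stemonopa insignis,KY352240,605,between trnS2 and trnP,67.60,No Repeat,-63.6,-62.3,3,45,False,False,
Anomura,Hippoidea,Hippidae,,Emerita talpoida,ON164669,553,between trnS2 and trnP,75.40,No Repeat,-62.4,-60.4,0,2,False,False,
Anomura,Hippoidea,Blepharipodidae,,Blepharipoda liberata,OK514627,611,between trnS2 and trnP,81.50,No Repeat,-180.5,-179.5,2,10,False,False,Temperate
Anomura,Galatheoidea,Porcellanidae,,Petrolisthes haswelli,LN624374,603,between rrnS and trnW,75.50,No Repeat,-70.8,-69.6,0,5,False,False,Tropical
Anomura,Galatheoidea,Porcellanidae,,Neopetrolisthes maculatus,KC107816,547,between rrnS and trnW,75.20,No Repeat,-67.8,-65.6,0,30,False,False,Tropical
Anomura,Galatheoidea,Porcellanidae,,Pisidia serratifrons,OM461359,371,between rrnS and trnM,83.00,53 x 2 bp,-56.6,-54.9,2,15,False,False,Temperate
Anomura,Galatheoidea,Galatheidae,,Allogalathea elegans,ON968875,1037,between trnE and trnF,75.10,No Repeat,-44.1,-43.2,0,146,False,False,
Anomura,Galatheoidea,Munididae,,Curtonida isos,MF457406,1557,between rrnS and trnS2,65.80,"2.4 x 11 bp; 2.1 x 292 bp",-77.3,-76.7,462,2756,False,False,
Anomura,Galatheoidea,Munididae,,Grimothea gregaria,KU521508,634,between rrnS and trnW,80.70,No Repeat,-79.4,-77.5,34,200,False,False,Temperate and subtropical
Anomura,Galatheoidea,Munidopsidae,,Shinkaia crosnieri,EU420129,327,between rrnS and trnQ,83.50,No Repeat,-23.5,-21.9,1200,1500,False,True,Deep-sea hydrothermal vents in tropical and subtropical regions
Anomura,Galatheoidea,Munidopsidae,,Munidopsis lauensis,MH717895,650,,73.40,"1.9 x 22 bp; 2.7 x 13 bp; 2.3 x 26 bp; 5.5 x 6 bp",-38.7,-37.3,1649,2000,False,True,Deep-sea hydrothermal vents in tropical and subtropical regions
Anomura,Galatheoidea,Munidopsidae,,Munidopsis verrilli,MH717896,647,,75.30,"3.0 x 11 bp; 1.9 x 15 bp; 3.9 x 12 bp; 2.3 x 19 bp",-58.3,-57.2,1575,4169,False,True,Deep-sea hydrothermal vents in tropical and subtropical regions
Anomura,Chirostyloidea,Kiwaidae,,Kiwa tyleri,KY423514,1525,between rrnL and trnW,90.50,(1.9-19.5) x (2-36) bp: 21 times,-198.7,-197.8,1000,2400,False,False,
Anomura,Chirostyloidea,Chirostylidae,,Sternostylus investigatoris,KY352237,1325,between rrnL and trnW,65.70,2.1 x 92 bp,-175.7,-175.0,299,957,False,False,Tropical
Anomura,Chirostyloidea,Chirostylidae,,Sternostylus rogeri,KY352238,1395,between rrnL and trnW,71.40,No Repeat,-152.5,-151.9,1364,1364,False,False,Tropical
Anomura,Lomisoidea,Lomisidae,,Lomis hirta,KY352239,2036,,73.40,2.6 x 119 bp,-133.5,-132.8,0,5,False,False,Temperate
Anomura,Aegloidea,Aeglidae,,Aegla longirostri,MF457407,428,between nad1 and rrnL,65.30,No Repeat,-46.2,-46.1,0,1,False,False,Fresh water
Brachyura,Portunoidea,Portunidae,,Portunus trituberculatus,MW232435,1532,between trnY and trnL1,64.50,No Repeat,-167.9,-166.9,0,50,False,False,Temperate and subtropical
Brachyura,Dromioidea,Dynomenidae,,Dynomene pilumnoides,KT182070,652,between trnL2 and trnL,80.40,No Repeat,-74.6,-73.2,10,100,False,False,Temperate and subtropical
Brachyura,Homoloidea,Homolidae,,Homologenus malayensis,NC026080,883,between rrnS and trnS2,75.60,9.9 x 42 bp,-134.1,-133.6,50,600,False,False,Tropic and subtropical
Achelata,Palinuroidea,Palinuridae,,Panulirus argus,,801,between rrnS and trnI,69.60,No Repeat,-99.2,-94.5,20,90,False,False,Tropic
Caridea,Alpheoidea,Alpheidae,,Synalpheus microneptunus,,834,,79.50,No Repeat,-104.0,-104.0,0,23,False,False,
Isopoda,Oniscoidea,Armadillidae,,Cubaris murina,,370,between trnS1 and trnL1,59.70,No Repeat,-103.7,-101.0,,,True,False,Tropic and subtropical
Stomatopoda,Parasquilloidea,Parasquillidae,,Faughnia haani,,1162,between rrnS and trnI,74.00,3.1 x 137 bp,-138.9,-137.8,72,230,False,False,
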