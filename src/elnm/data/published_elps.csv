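elp_label,region,member_ids,families,n_groups,n_languages
ELP 1,Highlands,00;08;16;18;19;24;29,TNG,7,95
ELP 2,Central NG,11;15,TNG,2,20
ELP 3,Southern NG,12;28,TNG,2,6
ELP 4,South-Eastern NG,23;36;37;38,"TNG, Austronesian",4,39
ELP 5,Northern NG + Bismarck Archipelago,33;34,Austronesian,2,59
ELP 6,South Papuan Basin,10,TNG,1,18
ELP 7,Huon Peninsula,21,TNG,1,61
ELP 8,Sepik-Ramu Basin,20,TNG,1,107
ELP 9,South-Eastern NG + South Papuan Basin,22,TNG,1,13
ELP 10,"Turama, Kikori, Purari River Basins",26,TNG,1,3
ELP 11,North-Eastern part of the Gulf of Papua,25,TNG,1,5
ELP 12,Gulf of Papua,27,TNG,1,6
ELP 13,South-Western NG,09,TNG,1,11
ELP 14,Biak Island,31,Austronesian,1,1
ELP 15,Manus Island + Central NG,32,Austronesian,1,23
ELP 16,Trobriand Islands,35,Austronesian,1,1
ELP 17,Papuan Tip,39,Austronesian,1,43
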