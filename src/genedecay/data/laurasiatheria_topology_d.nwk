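((Solenodontidae:75,(Talpidae:60,(Soricidae:50,Erinaceidae:50):10):15):5,(Chiroptera:76,(((Camelidae:68,(Suidae:64,((Hippopotamidae:55,Cetacea:55):6,(Tragulidae:52,Pecora:52):9):3):4):2,Perissodactyla:70):4,(Carnivora:60,Pholidota:60):14):2):4);
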