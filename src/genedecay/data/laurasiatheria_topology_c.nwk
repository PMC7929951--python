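((Solenodontidae:75,(Talpidae:60,(Soricidae:50,Erinaceidae:50):10):15):5,((Chiroptera:72,Perissodactyla:72):6,((Carnivora:60,Pholidota:60):14,(Camelidae:70,(Suidae:68,((Hippopotamidae:55,Cetacea:55):10,(Tragulidae:52,Pecora:52):13):3):2):4):4):2);
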