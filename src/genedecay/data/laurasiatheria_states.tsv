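Solenodontidae	lost
Talpidae	retained
Soricidae	lost
Erinaceidae	lost
Chiroptera	lost
Perissodactyla	lost
Carnivora	lost
Pholidota	lost
Camelidae	retained
Suidae	retained
Hippopotamidae	retained
Cetacea	retained
Tragulidae	lost
Pecora	lost
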