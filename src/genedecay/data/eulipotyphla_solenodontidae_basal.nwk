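(Solenodontidae:75,(Talpidae:60,(Soricidae:50,Erinaceidae:50):10):15);
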