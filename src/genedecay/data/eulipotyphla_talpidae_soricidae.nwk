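(Solenodontidae:75,((Talpidae:50,Soricidae:50):10,Erinaceidae:60):15);
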