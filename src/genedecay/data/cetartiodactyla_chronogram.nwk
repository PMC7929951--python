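(((Hippopotamidae:55,Cetacea:55):15,(Pecora:52,Tragulidae:52):18):10,(Suidae:65,Camelidae:65):15);
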