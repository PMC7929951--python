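(((Phyllostomidae:49,(Mormoopidae:35,Noctilionidae:35):14):11,(Vespertilionidae:54,Molossidae:54):6):4,Rhinolophidae:64);
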