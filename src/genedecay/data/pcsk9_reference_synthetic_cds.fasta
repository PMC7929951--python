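>PCSK9_synthetic_reference_cds 2079 bp, synthetic stand-in
ATGGTTTTCCTGTACCTCGATCCCCCTTATCAGGAGGTGCTCCGCAATACTCATGAAGGCATCGACATCC
ACCGCGCTGAGCCATCCACCGTGCTTACTGTCGCAAGCGCTGATGATACATTCAAGCGCAATGTCGTTGG
CCAGATCGCTGCATTAATCCTTGTCAATACCATTCGTCAAATTCAGAAACATAATGGAGCCATCTTAATC
CATGACAAGCGTAACATTGATTCTGACGAGGTCGAGTCCCTTCAACGCTCCGCCGGCTTCATTCGCAAAA
TCCACTTTAAGCGCTATTTTCAGTATAATACCGGCTCTAATGAGCATTGGATTTCCAAGTACTATGACAC
TGACAATACAATCAAGTGGGCACGCCTGTTTCGTTTTCACCAATTCGTGCGCCCCTGGTATTGGTATCTG
AGCCTGATCGATCTCCCACCTATCATTGAGTGGCCAGGTCACCACAAATCCGTCGCATGGCACAGAACCT
TCCCATTCCGTGAGACTTCCACTACTGAGGCACGTTTTCACACTAGCGTTCGCTGGGATCAGTATGATCA
TCGCTCTAAGGTCCCCAAAGATTGGACAGGAGATTGGTTTCATCCCGGCTCCCATAACAGACTGATCCAG
TTATCCGAACACGAATGGTCCAGAAAGGGAAACGAGTGTACCCCTCATTGGGGTACTAAGCAAAATTTCA
CATCCGAAGCAGCCTTCTCCTTTTGGACCACCGAGGGTCCTAAAGCTTCTTCCAATGGCGGTTGTGAACT
TACACAAGGCGCCGACGGTGTTAAGGAGGATATTGATAACGTTCAGGACTGGAAGAAGCAGAGAGGTTTT
CAATGGCTCTCCAACCACAGCTTATTTTTCACAAATGGTGAGTGGGCAAAAGATGCTTTCCTCGACTTTC
CTATTCTGAACGCCCCTGCCTACGAGCCCGGACTGACAAATTTCGCATTCATCAGATGTTTTGCCGAAAA
AATTCGTAACCTCAGACAGGCCTCCCTGATCGCAAACCAACGCTTCCATACCTGGGCTTACGTGCTGCAG
GTCCACAAGTGGGGTGTCTTTTGTACAGTTTACGAATGTAATGAGAGAAATCTGTTAGGTTGGCTCTACT
CCCACTTCCGCTGTTTTATTTGGTTAGGCCAGCGTAGCTCCCCAAGAGAAATTCGCGGAAACTTCATTGA
ATTCTCTAACCATACTCCCCGCAAGCGCACTAACCAGAATTTTTTCGTGGCCATCGAGCTGGTTAGACAG
GTTTGGGAGAAGCATCGCGGATGTCCTCATACCATCGAATGGCAGTACTTTGTTATTGACGAAGTCGAAT
TCCCAGAGCCTTTTAATAAATCCAAGCCCCCCCCATCCTGCATCTGGCCAGTTTGGGCTCACGGAACTCC
AGCTACTCAGGTCTGGAAGTGGAACTTTTGCAACCAGGATCCAGGTTACCTTAACTGTAGAGTGAAAGAA
CCAAGCGATCAGCGCCAGCTCGCCTGGAGAATCCAGGAAAAGTACGGTGGCGGAAAAACATACAGCTATA
AATGGCAACATCAAAAGGTTGCACAACTGGAGGAATCCTGTCACGACAAACGCTATCCTTGCTTATGGAG
CCACAACCTCTTCGGTGTCCATACTTGGAAGGTGAATGATGCATACCGTACTCCCGCCGATTCTTATGCA
CATTGTCGTCCTGATGTGAGCCCCTTAAAGAGAGTTGGTAAGAGCCGTGCCATCAATAACACTATTAAGC
AACAAGCTCAGTGTCTGGTTACCTCCCTCATTGAGGAGTCCATCGTGTGCTGTACTGACTACGCAGTCCG
TTGCTCTTGGCAATCCGTTACCACCGTTTGTTCCTGGTGGCGCTCTTGCAATCAGTACTGGCCCACCGAA
GGCATTTACGAATGCAATGACAAAAAAAAGCGTCGTCAATTAATTTCCCAGGGAAAGAGATGGTACTTCT
GTTTCGGTCATCATCCCGACTGTCTGCGTGATAATGTCCCCTGTGCATACCACTGTGTTAACAACCCTCG
CGAATGCCACTTCAATGACGGAGTCTATGGATTTGAGGATACTTTATAA
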