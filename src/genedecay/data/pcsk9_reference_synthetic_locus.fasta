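>PCSK9_synthetic_reference_locus synthetic stand-in
ATAATTCTCGCATGGCGAGGTCACCGCACTCTGCTCCCGGCGCCTTCAGTTCGGTTCTGTAAATGGTTCT
CAAGTTGTGCCCTACACATTAGCTGGGGCTAAGAAAGTTTACTTTTGTACGTTTGGTCTTGAGGTCCCGG
CCAGGATCGTCTAGAACCGGCCCCGTACAGGGCAGTCAACCTCCCATTCGCAACCCTAAGGCTCTCATGA
AAGAGCGAGCCGAGAAAGAGTAAACAGGTACTGATCCCGAGAAGGGCAGATCCTGCCACTCAAAAGCATT
CAGCTGGCCGTCATAGTCGAGCGGTGGAATACCCGCTCACCAGTTATCGCTTTGCTGCGCACGGTGTAGA
GGAAAGCCCACCATGGGAATCACCATGGTCCCCTTTTGCTGTCGACATTTTAGGACAGTTCCTTGGGATT
CTCTGTCAATGACACGAATTTTCTACTATACTGCGATCCGACCATTCCACCTTCAGAATCATCAACTAAA
AGCTTCAAGGAGATTGGAGAGTCTCCCACCCGACTATAATTACAGGAGCACTCTAAACCTGCGCTGTCCT
GTTCGGTGGCGCGACCTGCGACGTAGATGAGCTCAAACCGTGGCGGCGGACCGTCAAATTTCCTGGGTTC
GCGTTGGATAGGGGGTTGAATAGCACAGAACGTTAGGGACGGGTCAGGTAGCAAGATCGTGATAACGCCA
ATCTGGGTTGAAATTCCGTCTGGTTTCAGTACACCGTGCAGGGGTTGAGAACGGGTGCATGGCATAGGAC
GTGCTTGCACAGCTACCGGATCGCTTCCCTATGGTTTTCCTGTACCTCGATCCCCCTTATCAGGAGGTGC
TCCGCAATACTCATGAAGGCATCGACATCCACCGCGCTGAGCCATCCACCGTGCTTACTGTCGCAAGCGC
TGATGATACATTCAAGCGCAATGTCGTTGGTAGCGCTGTTGCCTGGGTGTCATCGGATCAGCAGTGGCCA
ACCTTTGCGTTTAGCCCACGAAACCCCAACCTTATAAGGCTGTCTAGTCCACACTATAAGAGATTACCAA
TGAACTTCTTATACGCACTTAGTACAATGTAGTGATTACACAAGCCACCACCGATCGACAGAAAAAAGAA
GGTGATTCACGTCGACTGTTTAGAGAAATTGCAGATGATGTCTGCAACCAAGGAAGAAACGGAAAGGAAA
TAAAACAGGCCTCCTGTTCTGAGACAGTCGCTAGGTGTTGGCTCTATTTCGGCGCCGTCGCCACGAGGGT
GGCGATGCAGAGCGGCTCTTCAAGAGCAGAAAATGCCAAGAGTCATAAATGAGCATACTACGTTTGAAGC
TACAGCGGATTCCAGCTTCACGACCGAAGGCCAGATCGCTGCATTAATCCTTGTCAATACCATTCGTCAA
ATTCAGAAACATAATGGAGCCATCTTAATCCATGACAAGCGTAACATTGATTCTGACGAGGTCGAGTCCC
TTCAACGCTCCGCCGGCTTCATTCGCAAAATCCACTTTAAGCGCTATTTTCAGTATAATACCGGCTCTAA
TGAGCGTATGGCAAAGGAGGAATTAGGGCGGGTGCTAAGGCTTCGTACTATTCGCGCATGAGATTGGTTC
AGTTCACATACGTACTCGGCCCCATAGCGGGGGATAGTGCCTAGCCTTATGGAATTTATGCACAACTTAC
TGGAGCCTTTGGGGGGATCACTACCGGGCGCTGGGGCGCACGAGTGGGGTCCTTAAGCACACAGACGCTT
AAGCTAATCGTACAATTCAGTGGGTACGGCTTGTAAAACAGGATTACCTACCAGTATATACGTCACTCCA
GATAACTTAGAGTCGCCCTGGGTGAGAGCTTGTAGATTGGATTTCCAAGTACTATGACACTGACAATACA
ATCAAGTGGGCACGCCTGTTTCGTTTTCACCAATTCGTGCGCCCCTGGTATTGGTATCTGAGCCTGATCG
ATCTCCCACGTGGCCATAAATCAAGAAGTGCCAGAGAGACCCAGGCATCATTTCTCGGTTTCACGACTCA
GCCTTTCATTCTGAGGGTCAGAAATTTCAGCAGTAGATTTTCTCTTTGCTTCCTGAAGCATAATTGTTAT
ACATTCACGCGTTGAACATTATAGCTGATACAATGAAAGAGAGGTGTCGTCGATCGTTTCCGCTAGTAAA
AGATGGGACGAACCAAGACGCAACCTCGTCGTAAGACGACGTTACCAGGTTGTCACTCCGCACGTATGGT
AAGGCTTGATGCACCTGACTACGCTAAGAGAGCTTGTGGTGACGCGTGACTCCCAAGCACTGGTCGCTAA
GCGCTTGCCTAGGCCTCGACGCAGCTATCATTGAGTGGCCAGGTCACCACAAATCCGTCGCATGGCACAG
AACCTTCCCATTCCGTGAGACTTCCACTACTGAGGCACGTTTTCACACTAGCGTTCGCTGGGATCAGTAT
GATCATCGCTCTAAGGTCCCCAAAGATTGGACAGGAGGTCTGGTTCCCCCATCTCGGACCCCCAATGTCC
CGCACCCTGGGAACTCCGAATGTGGCTCGACTAACTTTTTCATGGGGTACGGCCTTGTCTCGGGACACGC
CCCGCGAACCATCAATTCAGCAATGAGCCTGCGTACTATGTTACCCAAGGCTACAAGTACAATCGTAATC
AGGAGTCACCACCACTTTGTCACACTCCGGCCTCGGCCTCCGTGACTAGTCCTCTCCTAGATCTTGGCTG
CAAGGTTGGGCTGCTGTAGTTAGATGGTGAGCGAGAGATTGGTTTCATCCCGGCTCCCATAACAGACTGA
TCCAGTTATCCGAACACGAATGGTCCAGAAAGGGAAACGAGTGTACCCCTCATTGGGGTAGTTGGGTGCT
AGCACCCTCTTGAGTAAGTGGACGCACATCGGTGCTGATGTCAATACTCGCGAGATACTTTTTAAAATCC
TCAAGGTAGGGTGCAACGATTAAACCCCTAGCCTGTTCAAAGTGCCACTCCTGTGTACTACTTCCGATGT
TTAAAGCGTAATAACCAGAACACGGTAATCACACAACTCCATGGTAGTATCTTGGCAAGAGTTGATACTG
AAGGCCTACTCTGTGACCTACCCTGGTGTAGTATAGGGCTACTTGCTCGTGGCTTCATCCGAAGGATAAG
TGCGCATCCGCGCTAGAGGGGCAAGATCAGGAGGGTGGAGCTAAGCAAAATTTCACATCCGAAGCAGCCT
TCTCCTTTTGGACCACCGAGGGTCCTAAAGCTTCTTCCAATGGCGGTTGTGAACTTACACAAGGCGCCGA
CGGTGTTAAGGAGGATATTGATAACGTTCAGGACTGTGTGTAACTTCAGTGCCCCGAGATTGCTTAGTAG
TCTTCAATGAGACTCTTGATTATGATTAGTTCGGAAATCAGTACGCCGGTCCACTTGACTTCGCCACTAA
GTTGCCAAATAACTTCGGGGCATAACAAATAGTCTATAAAGCATTAAATGTCACTCACTAAAGGCGGTAC
TAGGCCACGGTGTTGGCCGCATTGAGAGGCGCCGCTTACATAGACAGCACCGTGGATACTAGGATTACGT
TGGAGCATTGTCATCAGTTGAAACGCAACTACTGTTCGATAGCTAGATGGGTATCGATTCAACCTGCCCT
TTATTCCGTCATGTGGATGCTCCCAGCAGTGGTAGGTCGCATTGCCACTCAATCCCCAAGCACTATTGTA
CTGTCGGGGCTCTAGCAAACGGAAGGGAAGAAGCAGAGAGGTTTTCAATGGCTCTCCAACCACAGCTTAT
TTTTCACAAATGGTGAGTGGGCAAAAGATGCTTTCCTCGACTTTCCTATTCTGAACGCCCCTGCCTACGA
GCCCGGACTGACAAATTTCGCATTCATCAGATGTTGTATACTATACCGTCTTCAGAATCCGTGTTTACTA
TTGCAGTGATATAGCAGCGAGGACTGCTCACCTTCAGCACGAGCCACCTCGATCCTAGATCTCCCATCTG
GACTACGTGTAATATTTCCATCGAACATTGCGTTGATTTAGGGACGTAAACCACTCTTACAGACGGGGCA
TCGGCTGGTGGGTTTTGAGAACTCTGCAGGACCGTTTCGAAAAAGGAAATCAATATGATTACCGGGTTAT
TCCATTCTGGTCGGAACAAGGCGCCCCGTTCCCTACATCATCAACGGAAGTTGCCGAAAAAATTCGTAAC
CTCAGACAGGCCTCCCTGATCGCAAACCAACGCTTCCATACCTGGGCTTACGTGCTGCAGGTCCACAAGT
GGGGTGTCTTTTGTACAGTTTACGAATGTAATGAGAGAAATCTGTTAGGTTGGCTCTACTCCCACTTCCG
CTGTTTTATTTGGTTAGGCCAGCGTAGTTTAAGGCACGGATGTACACACCAGGGGAAGATATACTGTCCA
TAAATTAAGGCGAGGAGCACATAGCCGAGAAAATACATGGATTATACAACCCGGTAAGTTCATACGTAAG
ACATTCGAGAGCAAGCCCTCATTGTTACACCCAACCTGTTCACACGGACAAGACACCAAAGTTCGCTTTG
CATTTCACCATATTGTTTGTCGAAAGATTGACGGTCATAATCGGCGGCGGAGCGCTTCTGCTCGGCCACG
GTCTACTAGCGTTGAGCCATAAGGCGATGGCTGTGTCAGCGACAGCAGGTTTGACTGGACTCATAACAGC
GACTACACTAAGATGGATGGAATGAGGCTCCCCAAGAGAAATTCGCGGAAACTTCATTGAATTCTCTAAC
CATACTCCCCGCAAGCGCACTAACCAGAATTTTTTCGTGGCCATCGAGCTGGTTAGACAGGTTTGGGAGA
AGCATCGCGGATGTCCTCATACCATCGAATGGCAGTACTTTGTTATTGACGAAGTCGAATGTCTGGGGCA
TTGTGTACGCCTGTATTACGATTTTCATAGATGCAAACCTTTGACTTGCAACGAGTTTGAAGGCTTAAGC
TGGGCGCCACCTTTGTAAAGAAGCTGGCGTGTCAACACGTAAGAGCTGACGAATAGGTACGGCCCTGCCG
GCTGGACCGGCAGACACGAAGTATGCTAACGCACGAGTCCAGTCAGTGGCTTAGGTAGAGTGCATCATAT
TCGCCATACACGGGCCAAGTAAAGCACTAATGCGCCGAACAGACCTAAGGCGGCATCTTTGAGAACTACG
ATGCGACCACAGGAGTCCCAGAGCCTTTTAATAAATCCAAGCCCCCCCCATCCTGCATCTGGCCAGTTTG
GGCTCACGGAACTCCAGCTACTCAGGTCTGGAAGTGGAACTTTTGCAACCAGGATCCAGGTTACCGTGGC
CAATCCTACCAAGGACAAGAACCCGCATGCTAGGACTGTGCATAAGTCCAGCTTTTGCCGAATACAACGG
AGATGCAAAACCAAGCTTCTTGTCAGACCTACTCCCCGTCTTGGGATTGGTCTCGGCTCAGTACATAAAA
TCACAGCTCAGCAATACCTTCTTTTGGAGTGGGGGGAAAACAGGATGTGGGCCCCATCGTACAACAAAAT
GTCCGAAACGTCCACGCTATTAGCAACAGTTTTGGCCGCTCTACAGGTTTTTCTCAAAGACCGCTGCTGA
GAACAGCCCTATCATACGCAGGAATCAGCTAACTCCGAATGGTACATAGGTACTGGAGTAACCTAACAAG
TAACCGTGGACGAGTTGGGGCAATGCGTAGTTAACTGTAGAGTGAAAGAACCAAGCGATCAGCGCCAGCT
CGCCTGGAGAATCCAGGAAAAGTACGGTGGCGGAAAAACATACAGCTATAAATGGCAACATCAAAAGGTT
GCACAACTGGAGGAATCCTGTCACGACAAACGCTATCCTTGCTTATGGAGCCACAACCTCTTCGGTGTCC
ATACTTGGAAGGTGAATGATGCATACCGTACTCCCGCCGATTCTTATGCACATTGTCGTCCTGATGTGAG
CCCCTTAAAGAGAGTTGGTAAGAGCCGTGCCATCAATAACACTATTAAGCAACAAGCTCAGTGTCTGGTT
ACCTCCCTCATTGAGGAGTCCATCGTGTGCTGTACTGACTACGCAGTCCGTTGCTCTTGGCAATCCGTTA
CCACCGTTTGTTCCTGGTGGCGCTCTTGCAATCAGTACTGGCCCACCGAAGGCAGTTTGGGGTCCAGAAA
CGGAAAAGCGAATTTACTGCGTGGAGCCGGCGCTTCCAATTGCTCAACGGTGTACCAGGTCATAGTCCAA
CATCAAGGTAGCAGTCGGTACCAGACTTGAATGACCCCGAGGGCGCGAAGGACCCTGTCTGGCCTAAAGT
CCTCTGTGGTTACATGGTAGAAGTATAACCAGGCGTCGTTGGTTTCTTAACGAGCGTCCATTGGGAGTAG
GTCGAGACCTACCCTGTCCGTATGCCGGGCTTACGCCACATGACCCGGAAAGAAGGAAACACATTGTTGA
CCGAGCCAACCTGGCTTGTTAGTTGATTGGCGGTCCCGCGCTAGTTTACGAATGCAATGACAAAAAAAAG
CGTCGTCAATTAATTTCCCAGGGAAAGAGATGGTACTTCTGTTTCGGTCATCATCCCGACTGTCTGCGTG
ATAATGTCCCCTGTGCATACCACTGTGTTAACAACCCTCGCGAATGCCACTTCAATGACGGAGTCTATGG
ATTTGAGGATACTTTATAATCGCATCCCGCTCAAACCTATCACAGAAAACGGCGAGCCTTATCCGTTGGC
GTCATATACACTGAAGCATTAAGGTGGATCCGAATAAACGCCTACATCGCGACTCGAGGCTTCGATCAAA
CCACGACAGGAAAAAGGGCTGTCGGTGTCCCTTAATTGTTACTGCAAGGGTTCCGAAAGTTATAGGCTCT
CTGGAAAATTACTGTCAGAAATTGCGACGACAAAGCAGCAGTCAAGGTCCTACAGACTTAGGGCGTGATG
AGCTCATAACTGCCCTGGGTCTGCGTAGTAAGCTCCTTTTTCTATGGTACAGGTATCGGTGCGTCCAGGT
CCTCATACATTCATTACCCTGATTGGGACGCGGTGAGTTCGACCTCCTTGGACGTGAGTATTTTCTTTAT
TCGATACACCACTACGCACAATTCATGCAGACTACTGTTTTTGAGGTTAATAGCCACGCCAGCAACATTA
TTAAGGATTAAGATAAGGAATGGACGGGCCATCGATTTCTCTGTTATCACATAACCCGGAAATTTACCTC
TTGTAGCCAGGACATGTTCTCTCTTACAGCTCCTTTTATGCACCGAGCACTGTACCACACAGGGTATCAT
GTGTGAATGTTCTACCGTAGCGAGCCGGCCTGAATTGCTGTATTGACGTATCAATCGTGACACATCGACG
GACGCGCGGCTGGAGACAGGACCTTCCACACCGGCGGGTGTCTAGACTCGTGCTTTTCTCCCTCCTTAGA
TGTCACATGAAAAATTTCTCGATGCACACTTGGGATCTGTATATACGCGCCATGTATCAAGACTTATTAA
GTCGCAATTTCCATTATATTTCGAGCAACATGGGTCGACTCTACCCGTGCAACCCTAATGGGAATACTAG
GTGGTTTAGCGTCTCGTTTACAGAAACGTAGAGGTATGCCCAGCCAACGACGGTTTTCGAGATAAGCCGC
CCTTGGTCCTTCTGAAGTGCTCCGCTATCGGGCTAGGAG
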