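>JAK2FRAG synthetic hotspot fragment
TCTTATTCCCGCACGGGTGGTCAGGCGAGGCGCGACAATTCATTCCCCTATTTTAAGTTG
GGAGATCGGTTCTAAGCACACATCACGCAATGTAAATGGTTTACACACGAGGAAGGTAGA
TCCAAAAAAGACATTGGGAACAGAATTGCCCAATTGATCAATCAATTGTCGCTGGGCTAA
TTGGCCCTCGCGAACCGTACTCACATGCCTCGTTGGCCTGGCAGGTCCGTGATATCATAA
CCAACCACAACCAATTCCTGCTCTCACCGAAGGTCCCGATTGGAGGGAGGGGGGATGCTT
TTGTTGGGATGTATCTTCTGTCAATTAAGGTAGCAACTATTTTCGATACATCCGTAACTC
GTAAACATGTCTTATCCTGTTCAAATTGTCCTGCAGACTTGACATATTCACACAGCCAAT
GCTGTGGGTTTAGTGCCGCTCACTATCCAAGAGAGTATTCAGTCGGAGCGAACACTATGT
TAAAAGCAGAACGCCCACGCTGCTGGGCCAGGTGGCACAACGATTGTAGACTCAAGGGGG
CGACGGCTGAATCCCACAGCCCCCTAGAATCACACCGAGAGCTCGTAGTTCCCGCCGTTG
GGTGATCGATGGACCACAGGCTTCAACCTATAACACCTGTGATGGATCAAGCTGGAGGAA
TGGGGGTAATGTCGGAATATCACACCCGGTATTATTGTCTGGTGGCACATCCATATTAAC
AGCCACACAGTCGGTACGTGCAAACCCGCCATACCAGTTTGAAGACAAAGGAAGAGGGCC
TGCCTACTTGGGCTTAGCACGGACAGGAAACCAGAGAGGACAAGGAGCCGGCGCATGTAC
CAATTCGATGGTCAAACTAATTTCTCTGACGAGTGGTATGGACATTGCAACGGATCTTGA
AGTAACTCCCCTAACAAGACTTCTCGGCTACCGTTAGCGAGCAAATTCGACACTTGCTAG
TTACTGGAGAGATGCAGTGAGTCCTATCATCAGACTGATCAACTTGCACAGTCTAGACAT
AAATGTCCCAATTCTTAGTACGTTGGTCAGGCGGGAAGAGATTCAGCCGGAGGTCGAAGT
TTCCAAAAGTATAATCTTCACTAGTACCGTCATTATTTATAAGGTACCTCATTTTAATCC
GACGCTTCAACATAAGGAGCCAGGAATCGTTTTTAGTGCGGAGTCAATTTTTAGGTCCAT
CGTTTGGGCTAAGAGGGGAAGTGGATGCTTGCTAGCCGGCGCAGTGGGTTCATTGCCTGA
CTAGCCCGTAATGCACTGATTTTTACTTTCTCTCTGTCCGGCCGGTGATAAACTCTAGGT
ATTAGGCAATGGGGGCCTACCCCCGCGACAACCTGGACCGCCATGCCAAGTTATGCTCAA
GATTGGATCCGAACGCTAGTGTGGAGACGACACGAGAGTTCCAGGGTAACCGGCCTCAGT
TAGGAAAAGTCCGACACAAGCAGGGCATAGAAATTATTTGGCCTCAAGCTTGGAGGTACC
CGACACCCAGTAAAGGATGCCTTACGACAGTTGGATGCGCTTGGGAACTGCAATCTCATC
CCCGCCTTAGTCCCAACCCATTGGTGGCGGACGAAGCGATTATCCGTCCTGTTAAGCTTG
TGGAAACTTACAGAATATGCTCAATCACAGTCCTGAGAATTAACAAAACAGCCGGTTCGC
GTGTGACATTAAGCCAAGCTAAATGACGTGCTCAAGTGATCAGGATTTTTGGCATTCCGC
GCCTGTTTAGGTAGCCGCCTGCTATGGATAGCAACTCCTGGTTGCTTGCAGCCGGGCAAA
CAGCTGACTGGAACTAACCTTCTCTTGGTCTCGTCATTGTACTCATGTGGGATCTGGTCA
TGCTGTGTGTGCCTAGGTTCGCATTTCCGCCAGTAAACCATCTCGCGAGCCTCTATAGCA
GATTTTCCGCAAGGTTTGTCACCTGCTCAGCACGCTATAGATGAACGAACTCCCAGGTAT
GGAAGTGCCTACGCAACTCG
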