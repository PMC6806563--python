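>chr1
GTAGGTTTACGCTGTACGTAGGAAGGGAGACGTGAGTCGGAGTGGGTATCGAGAGTGTGT
TTTGAATCAGGTGTTCTCAAAACGCTATAACATATGAGAACTAAAATCACAGTTCTGACT
ACGCGCTCGCCGATGGCAATCGAAGAATAAGGGATTATACGTCAATGTGCCAAGCTTACG
TTATGAGCCTAGGTTATTCGTGTATGAACACTCCTAGGGGTTGCGGTAAAGTACGTATCA
AAGGTAATGCGGCGTACGTAGCGCGACAGATGACGACCTCGCAACTGCCGGAGGAATAAC
CAAAGATGTATATGAATTGTAAGGGTATGGAAAACGGTCCGGCGATAAAGCTCATAATGC
GCTTGTAAATCGCCATATGCTGTTTAATAAGAATTGAACGTAAAGAGACGAGATAAGCCT
ACGCAAACGATTATGTATACAACCCTGATCAAAAGCGACGTATGACGGCGAAGGTGGTTT
CATCAGCAGGGACCCCTGGCGTTAACCATTCTCGAGGGGGTAATGATAAGATATTTCTTT
AAACTGTGACCACTGATTTAGTTGCGATAGTTCCGCCGGCAAATAGCGGGGTATCGGGTA
ACTACACTTAAGTTTTAAACATCCGGGGGTATTGCTTTTGTAGTTAATTTGTCTTATTCG
CTTTGCCGGCTTAGTAGAACTACCGCATACCAAATGTCTAAGGCTAGGACCCTAGTCGCA
AACTAATTATAATTAGTGGAAATTCCGCAGGGAGCAATTTACGCTCACATTTCTCAATAG
ATAAGACATATCATCTGGCAATGCAATTTCATTATAGCCGAACTGTTTAGCATCTATGAG
AGGGGCAATAATTACAATGAGTAAATCGAGGGGGGTGGAGAAGCAAAACTAGTACTATAC
TAATAGCTCAGCTAGTAATAGATCCATGCGTTGAGTTGCGTATCTGTTAGCTGTGTAGAA
CTACATTAGTGCTAAAACGTAATCAGGTTAGATACGACTCTTTGAGAGGGTGCTCGTGCC
CAGATGGACTTGGCACTCAAACTGCCTTGTAGCTGGCTTACGGAGAGCTAGTACAGGGGG
TAAAGAGACCATCGGCATGCTTATCAGTCAGACACATACTGGCTTACTCGGAGCCACTAC
CGATTCAGTGTTGTGGGATGGCAAATACACGATAAATGTATTTCGGTTGACTTCTCCCAG
GCGCCAAGCATAGTACGCGAGATTCGCGTTCCTCGCCCTGGACTCGCAGGTTACTGGAGC
CACGTGAATGCTCAAAGTGCAACGTCCGACGACTTTGTATTTCCACGCTTATCCGCATAG
AGACCAATACATGTAATGAGGTGAACGAAGCCGGTTCCCCTGTCGCCTCGAGGTGCCTTC
GGTTCCTCCATTAGCTAATGGGAACTAGGCGCCCACCAGATCTTAATTACGACGGTCAAA
ACTGAAGTTCTAGGCTGTTCGTTTAATTATCGCATGGTAGTGTTCCTAACTCCCTGGCCA
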