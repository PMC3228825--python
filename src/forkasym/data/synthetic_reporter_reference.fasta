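>synthetic_reporter synthetic 1.6 kb stand-in for the ura4:ura5 reporter (not a real locus)
GTTAATATTCAAACGGTTGTAAGAAGCTGGCAAATACATAATGTGTAGGTCGACCATCTGGGGACACATA
GATGATTTGAATGATGGCCAATCGCTACAATGCGTCGTCGTTATATTACTAGTGTAACACTGCATCTGGT
TGCTCTACGTATGTGTCCAAATTAGCGGATCGGAACTTTATTTGTAAAAAAGAGAGAATGTGGAGATTTA
CAAGTATTATTAGGGAGGTTCTTTAAGAGTCACGACAGTCCGAACCATGAATAAAATAATGACTCTATTT
GCAGTAAGTTAATGTTTTTCGATTTCCCATGCGTCTTCATTATTTAATAAGCTATATACAAATCATTTAC
AAAGAATCAGAGAGGGCTTAAATTATAGCTAAGAACTTTTTTTTAATATGCTAGATGTATTGTCCTTCGA
GTATATCCTGTAGGTACGGAGAATACTTGTCGTGGCGCTCCTGCTCTTCTACTGGGGGCAAACTCCCGTT
CATCTATACACTTCTCCGAATTATTCATAGCGACGGATAAAACTTAACTCTGGTTCACCACGAAAATAAA
CACAATAGCCTATTGAGGTATTAAATTTGGGGTGCGATTCTTCAAAACTATTTCATAATTAATATATAGA
GTAATGAGCTATGTCTTCATTATACTCAAAAAAACATTAGGAATCTAGTTAGCTAATCCTAACAAGTGGC
GTGTGAGCAGTAGTCACGTGATTAAATTACACTAACGTCACTTATATATACGGAAAAAACCGAACTACTC
TTATAACGTATCATTATAACTATGAGCGTGTATCTTTACTTCTCCTCCCCAATGGTAAAATCCGAATTAG
ACGACGGATATAAATAGTTAGGTCCAAGAACAATCATAATTGAAAAAAGAATCCATGGGAAGTTGGATAA
TTTCAATTATCAGACATGTTAATGAATGAGGCTTAACTGTGATATACTGACGAAAGCGAGATTCCTATAT
CGTATGCCAAGAGTTTTATATTGGAGAAATTAAAAAGCCAGACCTATATCGTGAATAATAAAACGAATTG
AGGCTCGAGTTATTCCTAGTGTCCATATCTTATGACAGACAGTTCGACTATGATATAATCAGAGTTAGTC
TATGTTTATAACGGTAACTGGTGAACTGACCGGTCCGTTCTCTAATATGGATATTAATCACACGTTACCT
AGTCAGCTAAATATTTAACTTATTTTTTCATACTGGTATTCCATAATGGTAACAGTGGAATAGATACGTT
TCATTATACGGTTCTCCCCAAACATTCGTCGCGTATGTGTCTAGTAATTGCGAGGGCATCTCAGGTTATA
TCCCGTGGCGCGCGACACAGTCAGATACCAAATTCTAGCATTAATTGTTTGACGTACATCTAGGCACTAA
CATTTTGATTTTTAGGCCACCCTTTTAGACTATTGTCCGAAATCATATTGCAAACCTGTTAGAATCAAGC
ATATCGCGTTACAAAATTTTACCACTAACGGTAAAATTTAATTGCCGTCAAATGTACTGACGTCATCTGA
AAAACCCTAATGCAGATTCATAGTTTCTCACCTTAACCTTTTGACATAAACTAATTGGAT
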