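>TRGV4.1
TGCATCAAAAAAATGCCGCACGGCAGAATACGTGGGTCCCGTGACTGCGTGAATTCTCCTTCCAGAGGTTCGTCTGCAGAACAACGCCGTGGCTAATGAGATTCGATCCGAGGGTCTCGCGCGCGGTCCCAGACAC
>TRGV1.1
ATCAACGAACTCTTAGACTCCGTGCCATGGTTGTTGACCAAAGGACGTTCGTTTGACTGAACTATCGGGTTCCCACTTGGGCCGATAACGAGAGCATCTGAGATTCTAAGCTGCCCTTTGTAGTAATCAAGCTTGA
>TRGV3.1
AACGACTAGGCTGGAGTCTTATCGATGCTTGTATCAAAGCAAGGGTGTGCAGTACACGGCATATGCACGCACGGACTCGGTTAGGCACGGGCGTTCTGATAGAGCTCTCAAGTGCCACAAGCCCAGCAATGTGCCCACGGA
>TRGV2.1
AAACGAGCACGCCGGACATGATCTAGTGTTGTATTATACCTAAGTTGCTCAACGTCATTGGCGGACCTGTTGTCCGGAGTGGGTCTCAATAATCCACCACAAGTCCCTCGGATGGGTTCACTTAAAGAATGTGGCCTCTAC
>TRGV2.2
GAACGTGCACGCCGGACATGATCAAGTGTTGTATTAACCCCAATTTGCTTAACGACAGTGGCGGCTGTTGTTCGGTGTGGGTCTCTATACTCAATCACAACTCCCTCGGATGGGTTCACTTAACGAAGGCCTCTAC
>TRGV2.3
AAACGTGCACGCCGGACATGATTTAGTGTTGTATTATGCCTAATATGCTTAACGTCCGTCGCGGCTGTTGTCAGGTGTTGGTCTCTATACTCGACCACAACTCCCTCGGATGGGTTCCCTTAACGAGGGCCTCTAC
>TRGV2.4
AAACTTGCACGCCGGACCTGGTATAGTGTTGTATTATACCTAATTTGCTTAACCTCTGTGGCGGACCTGTTTTCCGGGGTGGGTCTCTTTACTCCACTACAACTCCCTCGGATGGGTTCACTTAACGCATGTGGCCTCTAC
>TRGV4.2
TGCATCAAATAAATGCCGCACGGCAGAATACGTGAGTCTGGTGACTGAGAGAATACTCCTTCCGATTAAGTACGACTGCAGCTCAACGCCGTGACTAATGAGATTGGCTCCGAGGGTCTCACTCGGGGTTGTCCCAGACAC
>TRGV1.2
ATCAACGAACTTTTAGAGTCCATACCATGGTTGTTGAACAACGGTCGTTATTTTGACTGAACTACTTCGGGTTCGCTCTTTGGCCGAGGACGAGAGCATCTGGGATTCTAATCAGCACGCTGTAGTAATTGTCAAGCTTGA
>TRGV3.2
AGCATGTAGGCTGGAGTCGTATCGATTCTTGCATTAAAACAAGCGTGTCCAGTACCCGGTATATGTACGCAAGGACTCGGTTAGGAACGGGCGTGCTGATAGATCTCTCAAGTGCAACACGCCCAGCAATGTGCCCACGGA
>TRGV2.5
AAACGTACACGCCGGACATGATCTAGTATTGTATCATTCCTAATCTGCTTAACGTCTCTGGCGGCTGTTGTCCGGTGTAGGTCTCGATAATCCACCACAACTCCCTCGGATGGGTTCACTTAACGAAGGCCTCTAC
>TRGV2.6
AAACGTGCTCGCCAGACATGATCTACTGTTGTCTTACACCTAATTTGCTTAACGTCTGTGGCGACTGTGGTCCGGTGATGGTCTCTATACTCCACCACAACTCCCTCGGATGGGTTGACTTAACGAAGGCCTCTAC
>TRGV2.7
AAACGCGCACGCCGGACATGATCTAATGTTGTATTATATCGAAATTGCTTAACGTCTGTGGCGGACCTGTTGTCCGGTGTGGGTCTGTATACTCCACCACAACTCCCTCGGATGGGCTCACCTAACACATGTGGCCTCTAC
>TRGV2.8
AAACTTGCACGCCGGACCTGGTATAGTGTTGTATTATACCTAATTTGCTTAACCTCTGTGGCGGACCTGTTTTCCGGGGTGGGTCTCTTTACTCCACTACAACTCCCTCGGATGGGTTCACTTAACGCATGTGGCCTCTAC
>TRGV4.3
TGCATCAAAAAAATGCCGCACGGCAGAATACGTGTGTCTCGAGACTGATGGAATAGCCCTTCCAGAGGTACTACTGCAGCTAAACGCCGTGACTAATGAGATTGGGTCCGAGGGTCTCGCCCGCGGTCCCAGACAC
>TRGV1.3
ATCAACGATCTTTTAGACTCGGTCCGATGGTTGATGACCAATGGACTTTCTTTTCACTGAACTACTTCGGGTTCGCACTTGGGCCGAGAACGAGAGCATCTGAGATTCTCATCAGCACACTGTAGTAATTGTCAAGCTTGA
>TRGV3.3
AACATGTAGGTTGGAGTCGTAGCGATGCTTGCATCAAAGCAAGGGTGTGCAGTACCCGGTCAATGCACGCAAGGACTAGCTTAGGAGCGGTCGTGCTGATAGATCTCTCAAGTGCAACAAGCCCAGCAATGTGCCCACGGA
>TRGV2.9
CAACGTGGGCGCCGGACATGATCTAGTGTTGTATTATATCTAATTTGCTTAACGTCTGTGGCGGACCCGTGGTCCGGTGTGGGTCTCTATACTCCACCACAACTCCCTCGGATGGGTGCACTTTACTCATGTGGCCTCTAC
>TRGV2.10
AAACGCGCACGCCGGACATGTTCTATTGGTTTATTATACCTAATTTGCTTAACGTCTGTGGCGGCTGTTGTGCCGTGTGGGTCTCTATACTCCAACACAACTCCCTCGGAGGGGTTCAGTTAACGAAGGCCTCTAC
>TRGV2.11
AAACGGGCACGTCGGACATGATCTAGTGTTGTATTATACCTAATTTGCTTAACGTCTGTGGCGGACCTGTTCTCCCGTGTGGGGCTCGATACTCCTCCACAACTCTCTCGGATGGTTTAACTTAACGAATGTGGCCTCTAC
>TRGV2.12
ACACGTGCAGCTCGGACATGATCTAGTGTTGTATTATACCTAATTTGCTTAACGTCTGTGGCGGACCTGTTACCCGGTGTAGGTCTCTATACTCCACCAAAACTCCCTCGGATGGGTTCACTAAACGAGTGTGGCCTCTAC
>TRGV4.4
TGCATCAAAACAATGCCGCACGACAGAATACGTGGGTCTCGTGACTGTGTGAATCCTCCTTACAATGAGGTACGACTGTAGCTCAACTCCGAGACTAATGAGCTTGAATCCGAGGGTCTCGCTCGCGGTTGTCCCAGACAC
>TRGV1.4
ATCAACTAACGTTTAGACACCGTGCCATGGTTGTTGATCAATGGACGTTCTTTTGACTGAACTATCGGGTTCGGACTTGGGCCGAGAACGATAGCATCTGAGGTCCTAATGAGCACGCTGTAGTAATCAAGCTTGA
>TRGV3.4
AACAACTAGGCTTGAGTCGTATCGATGCTTGCATCAAAGCGAGGGAGAGCAGTACCCAGTATATGCACGCTAGGACTCGGTTAGGAACAGGCGCGCTGATAGATCTCTCAAGTGCATAAAGCCCAGCAATGTGCCCACGGA
>TRGV2.13
AAACGTGCACCCCGGGCATGCTCTTGTGTTGTATTATACCTAATTCGCTTAACGTCTGTGGCGGACCTGTTGTCCGGTGTGGGTCTCTATACTCCACCACAACTCCGTCAGATGAGTTCACATAACTAATGTGGCCTCTAC
>TRGV2.14
AAACTTGCACGCCGGACCTGGTATAGTGTTGTATTATACCTAATTTGCTTAACCTCTGTGGCGGACCTGTTTTCCGGGGTGGGTCTCTTTACTCCACTACAACTCCCTCGGATGGGTTCACTTAACGCATGTGGCCTCTAC
>TRGV2.15
AAACGTGCACGCCGGACATGATCTAGTGTTGTATTATACCTAATTTGCATAACGTCCGTGACGGACCTGTTGTCCGGTATTGGTCTCTATACTCCGACACAACTCCCTCGGATTGGTTCTCTTCACGAATGTGGCCTCTAC
>TRGV2.16
TAACGTGCCCGCGGCACATGATCTAGTGTTGTATTATACCTAATGTGCTTAACGTCTGTGGCGGCTGTTGGTCGGTGTGGGTCTCTATACTCCACCACAACTCCCTCGGGTGCTTTCACTTAACGAAGGCCTCTAC
>TRGV4.5
TGCACCAATGAAATGCCGCACGGCAGATTACGTGGGTCTCGTGACTGAGTGAATAGTCCTTCCCGAGGTACGAATGCAGCTCAGCGCCGTGACTAATGAGATTGGACCCGAGGTTCTCGCTCGCGGTCCCAGACAC
>TRGV1.5
ATCAACGAACTTTTAGACTCCGAGTCATGGTTCTTGACCATCGGACGTTCTTTTGACTGAACTACTTCGGGTTCGGATTTGGGCCGAGAACGAGAGCATCTGAGCCTCTGATAAGCACGCTGTAGTAATTGTCAAGCTTGA
>TRGV3.5
AACAACTGGCTTGGAGTCGTATCGATGCGTGCATTAAAGCATGGGTGTGCAGTACCCGGTATATGCACGAAAGGACTCGGTTAGGAAGGGGCGTGCTGATAGATCTCTCAAGTGCAACAAGCGCAGCTATGTGCCCACGGA
>TRGV2.17
AAACGTGCACGCCGGACATGAGCTAGTGTTGCATTTTCCCTAATTTGCTTACCGTCTGTGGCGGCTGCTGTCCGGTGTGGGTCTCTATACTCGACCACAACTCCCTTGGATGGGTTTCCTTAACGAAGGCCTCTAC
>TRGV2.18
AAACGCGCACGCCGGACATGATCTAATGTTGTATTATATCGAAATTGCTTAACGTCTGTGGCGGACCTGTTGTCCGGTGTGGGTCTGTATACTCCACCACAACTCCCTCGGATGGGCTCACCTAACACATGTGGCCTCTAC
>TRGV2.19
AAACTTGCACGCCGGACCTGGTATAGTGTTGTATTATACCTAATTTGCTTAACCTCTGTGGCGGACCTGTTTTCCGGGGTGGGTCTCTTTACTCCACTACAACTCCCTCGGATGGGTTCACTTAACGCATGTGGCCTCTAC
>TRGV2.20
AAACTTGCACGCCGGCCATGATCGAGTGTTGTATTATACCTATTTTGCTTAAAGTCTGTAGCGGACCTGTTGTCCGCTGTGTGTCTCTATCCTCCACCACAACTCCCTCGGATGGGTTGACTTAACGAATGTGGCCTCTAC
>TRGV1.6
TTCACCGAACTTTTAGACTCCCTGCCATGGTTGTTGACCAACGGACGTTCTTTTGAGCGAACTACTTCGGGTTCGCAAGTGGGGCGAGAACGAGACCATCTGAGATTCTAATTAGCACGCTGTAGTAATTGTCAAGCTTGA
>TRGV3.6
AAAAACTATGCTGGAGTGGTATCGACGCTTGCATCAAAGCAATGGTGTGCAGTACCCGGTATATGCACGCAAGGACTCGGTTAGGTAGGGGCCTGCTGATAGATCTTCCAAGTGCAACAAGCCCAGCAATGTGCCCACGGA
>TRGV2.21
CAGCGTGCACTCCGGACATGATCTTGTGTTGTATTATACATAATTAGCCTAACGTCTGTGGCGGCTGTTGTCCGGTGTGGGACTCTATAATCCACCACAACTGCCTCGGATGGGTTCACTTAACGAAGGCCTCTAC
>TRGV2.22
AAACGTGTACGCCCGCCATGATCCAGTGTCGTATTATACCTAATTTGCTTAACGTCTGTGGCGGACCTGTTGTCCGGTGTGGGTCCCTACACTCCACCACAACGCGCTCGGATGGGTTCACTTACCGAATGTGGCCTCTAC
>TRGV3.7
AACAACTAGACTGTAGTCGTATCGATGCTTGCAAGAAAGCAAGGGTCTGCAGTACCCGGTGTATGCACGCAAGGACTCGCTTAGGAACAGGCGTGCTGATATATCTCTCAACTGCAACAAGCCCAGCAATGTGCCCACGGA
>TRGJ1
CATAGCATTACGTTTCCCCGAGTCCCGTTTTTTGAAAAAGACTCAGAG
>TRGJ2
AACCATCGTAGTTTCGTCGGCTCGTCGTACCAGAAAAAGGATTTGGAT
>TRGJ3
TTCCTAGGACTATTTCATGGGTAACATCTGGACCCGGAGCGCGCTATA
>TRGC
AGAGACGGACCGGTCTTTCATACTCCCCCTACAGGGCAAACAACGATACAGGTTCAGTGGCATACCATAACTGGGACTATTATTGGGAGTTAGTCCTCCACAATTGATGCTCACATGCTA
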