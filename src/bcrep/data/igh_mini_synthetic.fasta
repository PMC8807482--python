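>IGHV1-7*01|V|IGHV1
TTTTCGGTGGTCGGCTGACGTGACTGCACACTAGTATGCATTTCTGAGTTAATCAAGATT
CTTGAATGTCTGTAGCCAGACCGGGCTCCTGAAGACTTATCTGGGTACGTAGAATAAGGT
AAATAACCTAAGAATAAGCTTCCACGCTGGGCGTACCGGTCAGCGTCGTTGCCTCCATTG
AAATAAATTTTGGGGGGGGATCTTCCGCTGCCGCCCGCCATGATCGCGGGTTACTTAGCA
AGCCTCTTTGCCGTATCGGCACTGTAATGACGTGGCTAAGTGTAGAACGTGTGGCTCG
>IGHV1-26*01|V|IGHV1
CAAATGTGTACCAATACGTTACGCTCGGACTAGAGGCATCCTGCGGCTGCGTGTGCTCAA
TCCACTACCGTAGGATATGCGACCAACGCGCTTGGCTCATACCCGCTCGAGAAACAGCCT
CAGTCTCGGCAAACTGAGCAAGCATCGCGCCGGGATATTCTAAGGAAGAGGGGAGCATTC
GGAGGCCAGCAGTTCTGATCGGAGGGACCATTGCAAGTTATCAGGGCGTTCCGCATGTGC
CGTCTGGTACCGTGACGCGGGCCTGAAAACGGCTAAAGAAGGTTGTGCGGGC
>IGHV1-82*01|V|IGHV1
ATAATAGCGGGATATCGCTCTCTTGCATTCTTAACCTGCTTGACTAAGGGATGTACCACA
GTCGTACCACTGTGGAAACGAACGATAGTAACTACCACGATGCGTAGGATTCACAATCAT
ACAATTAAAGGAGAAGCACTAACAGCCGTCCGCACGACAAGGAAACCCGCTATGGGCCTA
GATCCAGCGGCCGCCTCTGTTGGAGCCATCCCGACACCCCTTTCGGCGTTATACTAGATA
GGCGAAGGGCGGACCGAGTGGGAAAGGGGCTGTGTTGTCCGAGCTTTGTTGTGTA
>IGHV2-2*01|V|IGHV2
TCATGACGAAAGGATGGTGAATCTCCCGCTCTCAAGCGGAATGGCACCTCGTGATCATCT
TGGGACGGGCTCGTGGAGTCATAGAACTGTCATTTAGTGGACGGGTGCTTCAAGCCCCAC
TATACGTGAGGAACATAGCGCGTCTAGTTATCCCCTCGGTCCATTACGTGGGCTGTCCTT
ATTAGAGAGTATCTAGCGGCGTGAGTGAATGAAAATGTGCGGAAACGCCATTTTCTTTAC
AACCCCCTCGATACTTGTCCGAACCAGGTTATAGTGGAGAATAGCCACATGTTACGAG
>IGHV3-6*01|V|IGHV3
TGGTCACTTACAACTGTTATGGCCACGACGGGACGGCTGGCATAGCTTATGACTTTAAAT
CGAGGGTTGCGCTCCTAGGGTACTCCGGAACAAATGCTAGCGTGCAGGGCTCTACTAACC
CGTATTGGGTATTGCGGGTTAACACTTCATCGCCCTATCGGGGAGTAAGGGTAAAGGTAT
ATAGTCCGTGGGATACTCCCACAACATCCCTGACGATGTAAGGAATCGATAGCCCGAATG
ATGATCCGCGATATTGCTTAAGACACATGCGTAAACAGCAGTCCCGATTGTACCTTG
>IGHV5-17*01|V|IGHV5
CCCACAGATCGATAACGACGGCAATGTTGTCTAGGCTAGGTAACGCGAGCCCAGGGTCAG
GCGTCCTCTATACGCCGCGCGCATGAGTAAAATGAAGGCAATGTCTTCTGACGACTATGC
GGATTGGCCTACAGCGTGCATAGGAGTGTCTTGCTTTACGGCCATAGGATAGACAGGCAA
CTATATACGTCTGTTAGTGCCAGGGGTTCCTACTGTGTGTATTACACCCAACGCCTGTCA
CAAAACGAGCGCAGACCCCTCGGGGGCTAGAGAGGCAAACCCTGTTTGCTC
>IGHV6-3*01|V|IGHV6
ACCAAGAAGACTGTTATGAATGCCGCGAATTATAACAATAAGATAGGGGGATTGGGGAGC
GGCCTAGGACCGGTTCCAAGGTTATATCCGGTGGTGCGCGTTCGGTAAGCCGCGTACAAA
ATGTCTAGAGTGAAGGTATAAGGCCTGACCAATTACTAGCGGTTAAAACACACTACCAGA
AACTCTTTTCGGGGTCGGGTAACACCTCTCAGTAAGTGGCGAAATGCGTTAAGAGTGAAA
TTATAGAGTGACGCAAACTCTCCGGGGGGACAGATAGATGATTGTGTACCG
>IGHV9-3*01|V|IGHV9
GTCCTGTGGAGGGAATAGTGCACACAAACCCGAAGATATTGCTCTTCAGGTCGACGAAAA
CGTAAACGGAGCCTTCTTGCTTAATCTATTGATACGGTCGGACGGCATGCCTGCGCGCCG
GATATGTCGCCTATCTGGCTGAGAGGAGTGAGAGCCTCGCGCTCCACTTGTGTGGTTTTT
TAAGAGCTAAATGGGTCGGTTACGTACGACCTTCAAGTCCTAGCACTGAAAATGAAACTT
GATGTATTAACCCCTCTGCTACCACGTCTAACCGGGGTAACTACACTGTTCAGAT
>IGHD1-1*01|D|IGHD1
GGTCATGGCATG
>IGHD2-3*01|D|IGHD2
GTGCCATATCATGC
>IGHD3-1*01|D|IGHD3
CACGAGGTATGATGT
>IGHD4-1*01|D|IGHD4
GAAAGTCAGTCCCTGGT
>IGHJ1*01|J|IGHJ1
GAGGATCAGTTGGGTGGGTAATCTACAGAGAAAGACTGGAAAAGTATCCG
>IGHJ2*01|J|IGHJ2
CGCAAGCTGAGGTGGCTGCACAGGCTTCGTCACCGGTATACAGGGGGTG
>IGHJ3*01|J|IGHJ3
TCCTTCCTTTTTCGAGGGCTAGGGCTTTCAAAAGGGAGCAGGGTTTTCA
>IGHJ4*01|J|IGHJ4
GTACCAATTTGGCGTCGCACCGCGATGTCCTCTCCTGGAACAGGTAAC
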