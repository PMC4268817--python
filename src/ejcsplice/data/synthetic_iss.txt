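# synthetic stand-in ISS motif set (102 decamers);
# random motifs, NOT the published screen predictions
AAACACACGT
AAACACCCTT
AACAATACCC
AAGAGTCCCC
AAGATAAGAT
AAGCATTATT
AAGCGGTCGC
AAGCTACGGC
AAGGTGCTGA
AATCTTTGCG
ACACTACATG
ACCCACTGTA
ACCGTTGACC
ACTCTAGGGC
AGAACTGACG
AGATAATAGA
AGATCCAGCT
AGGATAGACC
ATACCCACGA
ATCCGACGCT
ATCTCAATCG
ATTTCCGGAG
CAAGTAAGGG
CAATGGCGGA
CACCGTAAGT
CACTTTTCCG
CAGCCCTGTT
CAGCGCATCT
CAGCTGAATC
CATAGTAGAG
CATCCATCTA
CCAAGGGTTG
CCCCAACCCC
CCCGTTTGTG
CCGAACTCAA
CCGCAACGGC
CCGGAAGACG
CCGGCGTGAA
CCTCTGGATG
CGACGGCTCG
CGAGAATTAA
CGAGGCCCTT
CGCACAGGCG
CGGGGTTTTA
CGTATGACTC
CGTTAGGGTA
CTACGTGTAC
CTAGGCGGCG
CTGAGCTAAC
CTGCCCACCT
CTGCTTACTG
CTGGAAGTCC
CTGGTCCCGA
CTTCTGTTCT
GAAGCGGTCA
GAATTATTGC
GAATTCACCC
GACCATCAGG
GAGGACGCCT
GATACCGCAT
GATCACAAGC
GATGTGTCAT
GCAATCCCGA
GCGCCTAATG
GCGGCGAAGT
GCTGCCCGAT
GCTTTGTCAA
GGAAATCTCA
GGAGCAATTT
GGCCCTTCAT
GGTAGAGTAA
GGTGTGGTGA
GGTTCGTCAA
GTCCGTGCCA
GTGGGTAAAG
GTGTTATTCC
GTTCTTAGGC
TAAATAACAT
TAACTATGAC
TAAGCCATAC
TAATTTGAGG
TACAGGATTC
TACGCGCACA
TACTCTCTCC
TATGAATACC
TCAGACGCGA
TCGGTACGCC
TGAATGGGAC
TGATAGTCGG
TGATGATGGC
TGGAGATTAG
TGGCGCGAGG
TGGGGTTTGT
TGTCATCAGG
TGTTGCCTGC
TTATCCATTT
TTATGAGACC
TTGCGGAGGG
TTGCTATTTT
TTGTAGTCCA
TTGTTCCACT
TTTATGTGAT
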