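# synthetic stand-in ESS motif set (176 hexamers);
# random motifs, NOT the published screen predictions
AAATGC
AACCCG
AAGATA
AAGCCA
AAGTAG
AATAAA
AATAGC
AATATT
AATCGG
AATTTG
ACACCC
ACATTG
ACCAAG
ACCGGA
ACGATC
ACGGCG
ACGGTA
ACGTTT
ACTAAT
ACTATG
ACTGTA
ACTTAC
AGAACA
AGAATC
AGACAT
AGAGGT
AGCCGA
AGCTAG
AGGATC
AGGTGC
AGTATT
AGTTGT
ATAGCG
ATGTCT
CAAGCC
CACAAC
CACAGC
CACCAC
CACGCA
CAGAGC
CAGAGT
CAGCCT
CAGCGA
CAGGGG
CAGTCG
CATCAC
CATCAG
CCAGTA
CCATGA
CCCCCC
CCCGCT
CCCTGT
CCGCAC
CCGGGC
CCGTAC
CCGTTC
CCTACG
CCTTTG
CGAAGA
CGAAGG
CGACTG
CGCATC
CGCCAG
CGCCGC
CGCCTA
CGCGAT
CGCTTT
CGGGGG
CGGTTG
CGTACC
CGTCAC
CTAGCT
CTCCAC
CTGCAG
CTGCGG
CTTATG
CTTGCG
CTTTTT
GAAAGC
GAACTC
GAACTT
GAATTC
GACAAC
GACTTA
GATACA
GATCGA
GATCGC
GATGGG
GATGGT
GCAGAG
GCAGGA
GCCATC
GCCCAG
GCCCTA
GCCGAT
GCGACG
GCGCAT
GCGTGG
GCGTTA
GCTCGT
GCTCTT
GGACGA
GGCCCC
GGCTCA
GGGACC
GGGCAC
GGGCGC
GGTCGT
GGTGGT
GTAAAC
GTAAGA
GTAAGG
GTACAC
GTAGTG
GTATCC
GTCCAT
GTCCCG
GTCCCT
GTCTAT
GTCTGT
GTCTTC
GTGAAT
GTGAGC
GTGTAG
GTTAGA
GTTAGT
GTTCGA
GTTTCA
TAAATA
TACAAG
TACCCT
TACGTT
TACTAG
TAGAAC
TAGCAT
TAGGTG
TATATA
TATCCC
TCACTA
TCACTG
TCCACC
TCGAAT
TCGACT
TCGAGG
TCGCGG
TCGTTG
TCTTCG
TCTTGG
TGAATT
TGATCA
TGCACC
TGCCTA
TGCGAT
TGCTCA
TGGCAA
TGTAGA
TGTCAC
TGTCCG
TGTGAT
TGTGTC
TGTTAT
TTAACA
TTAACC
TTAGCA
TTAGTA
TTATAA
TTCAAG
TTGCAC
TTGCGG
TTGCTG
TTGCTT
TTGTAC
TTTATC
TTTCTT
TTTGTA
TTTTGC
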