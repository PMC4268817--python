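# synthetic stand-in ESE motif set (238 hexamers);
# random motifs, NOT the published screen predictions
AAAATT
AAACGT
AAATCC
AAATGC
AACCGA
AACGAC
AACTGT
AAGAAG
AAGACA
AAGCAT
AAGCTG
AAGGCA
AATATA
AATCCA
AATCCT
AATGCC
AATGGG
AATGTG
ACAAGG
ACACAG
ACATGG
ACCATG
ACCGCT
ACCGGG
ACGGGA
ACGGGC
ACGTTA
ACTCAG
ACTTCC
AGAAGG
AGACAG
AGAGAG
AGAGGA
AGAGGT
AGATAA
AGATCC
AGATTG
AGCATT
AGCCGT
AGCTGA
AGGCGT
AGTGCC
AGTGTC
AGTTAG
ATAACA
ATAACT
ATAAGT
ATACAG
ATATTC
ATCGCG
ATCGTG
ATGATC
ATGGCC
ATGTTC
ATGTTT
ATTACA
ATTTAC
ATTTAG
ATTTCG
ATTTGA
ATTTTC
CAAAAT
CAAACA
CAAAGA
CAACCC
CAACTT
CAATAT
CACAAG
CACACA
CACAGA
CACGAA
CACTAA
CAGAGA
CAGATC
CAGCGC
CAGGCG
CAGTAT
CAGTCT
CAGTGT
CAGTTG
CATATT
CATCTC
CATTCC
CATTTT
CCAACC
CCACCT
CCACTC
CCAGCA
CCCAAA
CCCCTC
CCCGCT
CCCTAG
CCGAGA
CCGCAC
CCGCAG
CCGTAC
CCGTCA
CCGTCG
CCGTGA
CCTAAT
CGAATG
CGACGC
CGACTG
CGCATT
CGCCGG
CGCGGG
CGCGGT
CGCGTC
CGCTGA
CGGACA
CGGCTA
CGGGTG
CGGTAG
CGGTAT
CGTCTT
CGTGCC
CGTTGA
CTAAAC
CTAACC
CTCAAG
CTCGTA
CTCGTG
CTCTTT
CTGACC
CTGATT
CTGGAC
CTGTTC
CTTCCT
CTTGAC
CTTTCG
GAAGGC
GACCAT
GACGAG
GACGGT
GACTCG
GACTTT
GAGCAC
GAGCGC
GAGCTT
GAGGTA
GATCAC
GATTCC
GATTTA
GCAATC
GCACTG
GCATAG
GCCGAC
GCCTTG
GCGAAG
GCGACG
GCGAGG
GCGGTG
GCGTGA
GCGTGG
GCTAAA
GCTAGC
GCTCCC
GCTCTG
GGAAAA
GGACAA
GGCACG
GGCGAT
GGCTCC
GGGATT
GGGGTT
GGGTCC
GGTGAA
GTAAGA
GTAAGT
GTAGAC
GTAGCC
GTCCAA
GTCCGA
GTCGGG
GTGACC
GTGAGT
GTGTCC
GTGTCT
GTTCTG
GTTGCT
GTTTGG
TAAGGA
TAAGTT
TACACT
TACAGA
TACCCT
TACTTC
TAGATG
TAGCTA
TAGGTC
TAGTAG
TAGTCG
TATAAC
TATATT
TATTTA
TCAACG
TCACAC
TCCACC
TCCAGG
TCCATT
TCCCTC
TCCGCA
TCGAAG
TCGAGA
TCGTTA
TCTAAC
TCTCAT
TCTGAG
TCTTAA
TGAACA
TGACGT
TGAGGA
TGATCT
TGCACC
TGCAGG
TGCAGT
TGCATA
TGCCCG
TGCCGA
TGCTCT
TGGGAC
TGGGCC
TGGGGG
TGTAAG
TGTGCT
TTACGT
TTAGAT
TTATCA
TTATTG
TTCTAC
TTGAGA
TTGAGC
TTGGAA
TTTCGT
TTTGAC
TTTGAT
TTTGGG
TTTTGC
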