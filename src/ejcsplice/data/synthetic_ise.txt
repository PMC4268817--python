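# synthetic stand-in ISE motif set (199 hexamers);
# random motifs, NOT the published screen predictions
AAAAAA
AAAATG
AAACCA
AAATAT
AAATGT
AACACC
AACAGC
AACGAC
AACTTT
ACAAGA
ACAAGT
ACACAA
ACAGCT
ACAGGG
ACCAAA
ACCATC
ACCCCT
ACCGCA
ACCGCG
ACCGGC
ACGAAT
ACGCAA
ACGCCG
ACGCGC
ACGGTA
ACTGTG
ACTGTT
AGAGAC
AGATGC
AGCCTT
AGGCTA
AGGTGA
AGGTGG
AGGTTC
AGTCAG
AGTCGC
ATATGA
ATCCTA
ATGCAC
ATTCAA
ATTGAG
ATTTGG
CAATCC
CACAAA
CACAAT
CACAGG
CACCAT
CACCTC
CACGCA
CAGGGC
CATAAA
CATATT
CATCGG
CATGAA
CCCCGC
CCCTGG
CCGATT
CCGGTT
CCGTCG
CCTATT
CCTCGC
CGAACC
CGACTG
CGAGCC
CGATAG
CGCACT
CGCGCA
CGCTTC
CGGATC
CGGCGT
CGGGCC
CGGGCT
CGGGTA
CGGTGT
CGGTTT
CGTGCT
CGTTCA
CTAACA
CTAGCA
CTAGTT
CTCAAC
CTCCTA
CTCGAA
CTCGCC
CTGAAT
CTGCCC
CTGCGT
CTGCTT
CTTCAC
CTTCTC
GAAACT
GAAATC
GAAGAG
GAAGAT
GACACC
GACATC
GACGCA
GACGTT
GACTAT
GACTCC
GAGATT
GAGGGA
GAGGTT
GATCCG
GATCTT
GATGTT
GATTTC
GCAAAG
GCAATG
GCACTC
GCAGAT
GCCACG
GCCCCA
GCCGCA
GCGATC
GCGGCA
GCGGCT
GCGGGG
GCGGGT
GCTCAG
GCTCTC
GCTCTG
GCTGTC
GCTTAC
GGAAAC
GGAAGT
GGAGCG
GGAGTA
GGATCT
GGATGT
GGCTCA
GGCTGA
GGGAAC
GGGGTA
GGTAAG
GGTATA
GGTTTG
GTAACT
GTAATT
GTACCG
GTCCCG
GTCGCG
GTCTGC
GTGGAA
GTGGCG
GTGGGC
GTGTAA
GTGTTA
GTTACC
GTTGTC
GTTTTT
TAAACG
TAACGG
TAACTT
TAAGAG
TAATAT
TACACA
TAGACC
TAGCCC
TAGTCG
TAGTGA
TATAAG
TATACA
TATACC
TATTCT
TCATAG
TCATCC
TCATTG
TCCCAA
TCCCGC
TCCGGG
TCCGTC
TCCTAC
TCGACT
TCGGCA
TCGTCC
TCTAAT
TGAGTT
TGATGC
TGCATA
TGGCGC
TGGCTG
TGGGAA
TGGGAT
TGTAGA
TGTAGC
TGTCAC
TGTTAT
TTCCGC
TTCCTA
TTCTTG
TTGAAC
TTGCCA
TTGTAC
TTTAGG
TTTCAT
TTTCCT
TTTTAC
TTTTGT
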