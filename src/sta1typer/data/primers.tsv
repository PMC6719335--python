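name	sequence	category
STA1_Full_Fw	TGGAATGAACAGCGCCAAGT	sequencing
STA1_Full_Rv	AGTGGGAGAAAAAGGTGGCC	sequencing
STA1_24_F	AATGAACAGCGCCAAGTAGC	sequencing
STA1_546_R	TTGAAAGCTATGTGCAGTTGG	sequencing
STA1_482_F	TGTCCCCTAATGTATCCCTCA	sequencing
STA1_1148_R	AAATCTTACCCGTGGATCCTTT	sequencing
STA1_1055_F	CCCAAAATTCATTCGTAGCC	sequencing
STA1_1768_R	TATGCGATGTCCCAGTACGA	sequencing
STA1_1671_F	TGTCAGGCATTGCACAAACT	sequencing
STA1_2384_R	CAATTGAGAACCCTTCAACAA	sequencing
STA1_2267_F	AGGGCAGTTTTATTTACCTTAACA	sequencing
STA1_2951_R	AAGTGGTTGTTGATTCCGATG	sequencing
STA1_2901_F	TCCATGTTCAACCAGTCCAA	sequencing
STA1_3550_R	CTGTCGCTGGAGCCACTC	sequencing
STA1_3474_F	CTTGATGAATGGGACAGTGG	sequencing
STA1_4169_R	GACCGTTCTGAGGCGTTAAA	sequencing
STA1_4051_F	TGGAATTCTTCCGGATTTGA	sequencing
STA1_4746_R	GGTTTGATTGAAGGCAGGTG	sequencing
STA1_4657_F	AGCGAGCTGGTATTCTCCAA	sequencing
STA1_5201_R	ACACGCTTTGGACATCATCA	sequencing
SD-5A	CAACTACGACTTCTGTCATA	sta1_detection
SD-6B	GATGGTGACGCAATCACGA	sta1_detection
STA1_UAS_Fw	CCTGGCTCAAATTAAACTTTCG	promoter_detection
STA1_UAS_Rv	ACCACCAATAGGCAATAGAAA	promoter_detection
STA1_UAS_Q_Fw	CAAGGCAATCAGTTAAAAGA	promoter_detection
Sdia-f	TTCCAACTGCACTAGTTCCTAGAGG	qpcr
Sdia-r	GAGCTGAATGGAGTTGAAGATGG	qpcr
UBC6_F	GATACTTGGAATCCTGGCTGGTCTGTCTC	qpcr_reference
UBC6_R	AAAGGGTCTTCTGTTTCATCACCTGTATTTGC	qpcr_reference
ALG9_F	CACGGATAGTGGCTTTGGTGAACAATTAC	qpcr_reference
ALG9_R	TATGATTATCTGGCAGCAGGAAAGAACTTGGG	qpcr_reference
repair_oligo_promoter_deletion	GACGGGGTATTATGAATAAAGGATCCACGGGTAAGATTTGCTGCGCTCTCTTCTAGTTCAAGAACGGATAACTCATAGAC	repair_oligo
repair_oligo_orf_deletion	GACGGGGTATTATGAATAAAGGATCCACGGGTAAGATTTGACAAAAAAAAATAAAAGAAAAGCGAGAAGTATACACAAGT	repair_oligo
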