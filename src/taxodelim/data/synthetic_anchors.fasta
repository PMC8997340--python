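>ssu_3prime synthetic stand-in for the 3'-terminal 16S rRNA fragment flanking the ITS
CCTAGCTGCCCGTTAAGGAGAAACGCTGCCGCTATAGGGG
>lsu_5prime synthetic stand-in for the 5'-terminal 23S rRNA fragment flanking the ITS
GCCGAGGGTGAGTAGCTACTGGCCCTACTGCGTCGAGAGT
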