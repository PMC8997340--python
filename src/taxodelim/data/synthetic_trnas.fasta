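>tRNA-Ile synthetic stand-in, 74 nt, bundled reference for spacer tRNA localisation
CATGTAGCGTGCGTACGCCTACGTATGAAGATTGCCCTTAATCGGGTTCATCGCATGGAC
TTGGAGTACACTGT
>tRNA-Ala synthetic stand-in, 73 nt, bundled reference for spacer tRNA localisation
CAGGTCCAGCGCTAGAGACAATGCCAGGTATTGGTTGTTCTAGAGAACATGGGGTCTATG
GCCAATTAACCAA
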