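"""Nine previously reported *A. gossypii* candidate novel miRNAs (mature and
precursor, RNA-space, preserved verbatim from the original report).

Known typesetting quirks are kept, not corrected: ago-miR-C7's mature
contains internal spaces; ago-miR-C4's precursor mixes U and T in one
sequence; ago-miR-C5's mature overruns the printed precursor end by 2 nt
(mature ends ...UGUG, precursor ends ...UUUG), so after canonicalization
exactly 8 of the 9 matures are substrings of their precursors.
ago-miR-C1 and ago-miR-C3 share one printed precursor.
"""

CANDIDATES = {
    "ago-miR-C1": (
        "GUCCACGGCGGUCGUCGAGCGC",
        "GUCCACGGCGGUCGUCGAGCGCGGCCGCGCCAUCCGCGUCCCGGCGUUCGG",
    ),
    "ago-miR-C2": (
        "GGGCGGUCCGGCCGCCGCGCCAUCGG",
        "GUGUCGCGGCCGUUUGACCGCCUUUUCGUCGGUUUGCCGUCACCGGGCGGUCCGGCCGCCGCGCCAUCGG",
    ),
    "ago-miR-C3": (
        "GUCCACGGCGGUCGUCGAGCGCGGC",
        "GUCCACGGCGGUCGUCGAGCGCGGCCGCGCCAUCCGCGUCCCGGCGUUCGG",
    ),
    "ago-miR-C4": (
        "ACAACCUCUGGCGGUCGUGGGA",
        "GACAACCUCUGGCGGUCGTGGGAUUCUAUCAAGUUUCCUUCGGCUCAGCCAGCGGUUUUUUA",
    ),
    "ago-miR-C5": (
        "AAAUUCGGUUCUAGAGAGGUUUGUG",
        "UACCCUGUAGAUCCGAAUUUGUUUGAAAAACGGCGACAAAUUCGGUUCUAGAGAGGUUUG",
    ),
    "ago-miR-C6": (
        "CUCGGAGUGUUAGUUACCGGC",
        "CUCGGAGUGUUAGUUACCGGCACGUCGGCCCGGACGUAUUGUCGGCAGGCGGACACGUGUCUC",
    ),
    "ago-miR-C7": (
        "CAAGUC GGUGUGGCG CGGCGU",
        "CAAGUCGGUGUGGCGCGGCGUCGAGGCCAAGAUUGACAUGUGCCGGUCGUCGCAUCCCAUGUA",
    ),
    "ago-miR-C8": (
        "GGACGUAUUGUCGGCAGGCGA",
        "GCUUGUCAGCCGUCCGGGGUGUUAGUUACGUCGGCCGGACGUAUUGUCGGCAGGCGA",
    ),
    "ago-miR-C9": (
        "CGUCGUCCCGUCGCGUCGUCAG",
        "CGUCGUCCCGUCGCGUCGUCAGUUUGCCGUCGGUUCGCCGGCGCGCUACUGGCGCGCGGCGUGGUCGCCGUG",
    ),
}

#: The one candidate whose printed mature is not contained in its precursor.
OVERRUNNING = "ago-miR-C5"
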