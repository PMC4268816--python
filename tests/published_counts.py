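"""Published codon-usage counts for the Taenia saginata cysticercum transcriptome.

Two printed tables from the published codon-usage survey of the 11,399-CDS
T. saginata transcriptome serve as fixed numeric inputs for recomputation
tests: the whole-dataset codon counts with their printed RSCU values
(six families), and the complete 5%-CAI-extreme high/low expression pools
with printed RSCU and the published optimal-codon stars.

Codons are RNA-spelled as printed. Values are transcribed integers/decimals;
nothing here is computed.
"""

# whole-dataset counts and printed RSCU: codon -> (count, printed_rscu)
TABLE1_FAMILIES: dict[str, dict[str, tuple[int, float]]] = {
    "Phe": {"UUU": (99671, 0.97), "UUC": (106107, 1.03)},
    "Leu": {
        "UUA": (38856, 0.45),
        "UUG": (97522, 1.13),
        "CUU": (107259, 1.24),
        "CUC": (119595, 1.38),
        "CUA": (52511, 0.61),
        "CUG": (103594, 1.20),
    },
    "Tyr": {"UAU": (55514, 0.81), "UAC": (81868, 1.19)},
    "His": {"CAU": (62791, 0.95), "CAC": (68855, 1.05)},
    "Lys": {"AAA": (115265, 0.92), "AAG": (135856, 1.08)},
    "Val": {
        "GUU": (95565, 1.12),
        "GUC": (85970, 1.00),
        "GUA": (45908, 0.54),
        "GUG": (115101, 1.34),
    },
}

# high/low CAI-extreme pools:
# codon -> (amino acid, rscu_high, n_high, rscu_low, n_low, starred_optimal)
TABLE2: dict[str, tuple[str, float, int, float, int, bool]] = {
    "UUU": ("Phe", 0.69, 2341, 1.23, 3032, False),
    "UUC": ("Phe", 1.31, 4441, 0.77, 1907, True),
    "UUA": ("Leu", 0.20, 540, 0.90, 1844, False),
    "UUG": ("Leu", 0.96, 2598, 1.35, 2759, False),
    "CUU": ("Leu", 0.95, 2570, 1.34, 2750, False),
    "CUC": ("Leu", 1.97, 5332, 0.79, 1628, True),
    "CUA": ("Leu", 0.41, 1099, 0.74, 1516, False),
    "CUG": ("Leu", 1.52, 4118, 0.88, 1804, True),
    "AUU": ("Ile", 1.02, 2797, 1.43, 3065, False),
    "AUC": ("Ile", 1.61, 4442, 0.78, 1677, True),
    "AUA": ("Ile", 0.37, 1025, 0.79, 1702, False),
    "AUG": ("Met", 1.00, 4032, 1.00, 3118, False),
    "GUU": ("Val", 0.67, 1925, 1.40, 2912, False),
    "GUC": ("Val", 1.14, 3248, 0.79, 1635, True),
    "GUA": ("Val", 0.37, 1061, 0.77, 1598, False),
    "GUG": ("Val", 1.82, 5203, 1.05, 2177, True),
    "UAU": ("Tyr", 0.50, 1151, 1.13, 1851, False),
    "UAC": ("Tyr", 1.50, 3424, 0.87, 1414, True),
    "CAU": ("His", 0.65, 1279, 1.23, 1936, False),
    "CAC": ("His", 1.35, 2642, 0.77, 1216, True),
    "CAA": ("Gln", 0.71, 2117, 1.18, 3336, False),
    "CAG": ("Gln", 1.29, 3842, 0.82, 2309, True),
    "AAU": ("Asn", 0.79, 2261, 1.28, 3935, False),
    "AAC": ("Asn", 1.21, 3495, 0.72, 2199, True),
    "AAA": ("Lys", 0.62, 2293, 1.10, 4690, False),
    "AAG": ("Lys", 1.38, 5114, 0.90, 3805, True),
    "GAU": ("Asp", 0.87, 3333, 1.24, 4539, False),
    "GAC": ("Asp", 1.13, 4308, 0.76, 2767, True),
    "GAA": ("Glu", 0.56, 2716, 1.13, 6131, False),
    "GAG": ("Glu", 1.44, 6946, 0.87, 4759, True),
    "UCU": ("Ser", 0.80, 1672, 1.26, 2823, False),
    "UCC": ("Ser", 1.51, 3157, 0.87, 1951, True),
    "UCA": ("Ser", 0.74, 1540, 1.32, 2967, False),
    "UCG": ("Ser", 1.06, 2216, 0.79, 1772, True),
    "AGU": ("Ser", 0.85, 1770, 1.03, 2318, False),
    "AGC": ("Ser", 1.03, 2150, 0.73, 1640, True),
    "CCU": ("Pro", 0.91, 1919, 1.21, 2292, False),
    "CCC": ("Pro", 1.32, 2776, 0.74, 1399, True),
    "CCA": ("Pro", 0.89, 1875, 1.45, 2734, False),
    "CCG": ("Pro", 0.87, 1821, 0.60, 1139, False),
    "ACU": ("Thr", 0.96, 2294, 1.21, 2521, False),
    "ACC": ("Thr", 1.49, 3545, 0.83, 1731, True),
    "ACA": ("Thr", 0.70, 1678, 1.25, 2607, False),
    "ACG": ("Thr", 0.85, 2015, 0.71, 1486, False),
    "GCU": ("Ala", 1.00, 3271, 1.31, 3013, False),
    "GCC": ("Ala", 1.38, 4515, 0.80, 1840, True),
    "GCA": ("Ala", 0.71, 2315, 1.28, 2935, False),
    "GCG": ("Ala", 0.92, 3009, 0.62, 1417, True),
    "UGU": ("Cys", 0.79, 1441, 1.08, 1673, False),
    "UGC": ("Cys", 1.21, 2188, 0.92, 1416, True),
    "UGG": ("Trp", 1.00, 2015, 1.00, 1293, False),
    "CGU": ("Arg", 1.60, 2637, 0.93, 1267, True),
    "CGC": ("Arg", 1.88, 3105, 0.61, 830, True),
    "CGA": ("Arg", 0.99, 1639, 1.03, 1414, False),
    "CGG": ("Arg", 0.71, 1176, 0.63, 858, False),
    "AGA": ("Arg", 0.34, 567, 1.62, 2220, False),
    "AGG": ("Arg", 0.48, 795, 1.18, 1612, False),
    "GGU": ("Gly", 1.40, 3673, 1.18, 2195, True),
    "GGC": ("Gly", 1.46, 3819, 0.80, 1487, True),
    "GGA": ("Gly", 0.66, 1742, 1.39, 2572, False),
    "GGG": ("Gly", 0.48, 1252, 0.62, 1158, False),
}

# printed concatenated-dataset positional GC contents and their printed mean
PRINTED_GC_POSITIONS = (0.534, 0.439, 0.535)
PRINTED_GC_OVERALL = 0.503


def high_pool_counts() -> dict[str, int]:
    """High-expression pooled counts, DNA spelling."""
    return {codon.replace("U", "T"): v[2] for codon, v in TABLE2.items()}


def low_pool_counts() -> dict[str, int]:
    """Low-expression pooled counts, DNA spelling."""
    return {codon.replace("U", "T"): v[4] for codon, v in TABLE2.items()}


def starred_codons() -> set[str]:
    """Codons printed as significantly preferred in the high pool (RNA spelling)."""
    return {codon for codon, v in TABLE2.items() if v[5]}
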