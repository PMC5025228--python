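"""Independent brute-force oracles used to freeze expected test values.

These deliberately avoid the library's own mass/alignment/statistics code
paths: masses are rebuilt from elemental compositions and atomic masses,
alignments by exhaustive ungapped scanning, chi-square from the textbook
cell-by-cell formula.
"""

from collections import Counter

# CODATA/IUPAC monoisotopic atomic masses (Da)
ATOM = {"C": 12.0, "H": 1.00782503207, "N": 14.0030740048,
        "O": 15.9949146196, "P": 30.97376163}

# Elemental composition of internal residues (nucleoside monophosphate - H2O)
RESIDUE_FORMULA = {
    "A": Counter(C=10, H=12, N=5, O=6, P=1),
    "C": Counter(C=9, H=12, N=3, O=7, P=1),
    "G": Counter(C=10, H=12, N=5, O=7, P=1),
    "U": Counter(C=9, H=11, N=2, O=8, P=1),
}
CH2 = Counter(C=1, H=2)
H2O = Counter(H=2, O=1)
HPO3 = Counter(H=1, P=1, O=3)

# Neutral nucleobases (BH) for a-B ions
BASE_FORMULA = {
    "A": Counter(C=5, H=5, N=5),
    "G": Counter(C=5, H=5, N=5, O=1),
    "C": Counter(C=4, H=5, N=3, O=1),
    "U": Counter(C=4, H=4, N=2, O=2),
    "m1A": Counter(C=6, H=7, N=5),
}


def formula_mass(formula: Counter) -> float:
    return sum(ATOM[el] * n for el, n in formula.items())


def oligo_formula(residues, five_prime="OH", three_prime="P") -> Counter:
    """Molecular formula of a linear oligo from residue compositions.

    ``residues`` is a list of (base, n_methyl) pairs.
    """
    total = Counter()
    for base, n_methyl in residues:
        total += RESIDUE_FORMULA[base]
        for _ in range(n_methyl):
            total += CH2
    if three_prime == "cyclicP":
        extra = Counter() if five_prime == "OH" else HPO3
    elif (five_prime, three_prime) in (("OH", "P"), ("P", "OH")):
        extra = H2O
    elif (five_prime, three_prime) == ("OH", "OH"):
        total = total + H2O
        for el, n in HPO3.items():
            total[el] -= n
        return total
    else:
        extra = H2O + HPO3
    return total + extra


def oligo_mass_oracle(residues, five_prime="OH", three_prime="P") -> float:
    return formula_mass(oligo_formula(residues, five_prime, three_prime))


def chi2_oracle(a_mod, a_un, b_mod, b_un):
    """Textbook Pearson chi-square on a 2x2 table, cell by cell."""
    n = a_mod + a_un + b_mod + b_un
    rows = (a_mod + a_un, b_mod + b_un)
    cols = (a_mod + b_mod, a_un + b_un)
    obs = ((a_mod, a_un), (b_mod, b_un))
    stat = 0.0
    for i in range(2):
        for j in range(2):
            e = rows[i] * cols[j] / n
            stat += (obs[i][j] - e) ** 2 / e
    return stat


def ungapped_anchor_oracle(query, target, centre_idx, match=2, mismatch=-1):
    """Best ungapped placement of ``query`` on ``target``; returns the
    1-based target position aligned to query index ``centre_idx`` and the
    best window score."""
    best_score, best_off = None, None
    for off in range(len(target) - len(query) + 1):
        score = sum(match if query[k] == target[off + k] else mismatch
                    for k in range(len(query)))
        if best_score is None or score > best_score:
            best_score, best_off = score, off
    return best_off + centre_idx + 1, best_score


def iupac_scan_oracle(seq, motif, codes):
    s = seq.upper().replace("T", "U")
    hits = []
    for i in range(len(s) - len(motif) + 1):
        if all(s[i + j] in codes[c] for j, c in enumerate(motif.upper())):
            hits.append(i + 1)
    return hits
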