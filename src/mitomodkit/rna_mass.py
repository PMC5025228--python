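"""Modification-aware in-silico nuclease digestion and oligonucleotide MS math.

Implements the computational core of LC/ESI-MS identification of methylated
rRNA fragments: RNase T1 / RNase A digestion that respects 2'-O-methyl
blockage of cleavage, monoisotopic neutral masses of modified oligomers with
explicit terminal chemistry, negative-mode m/z, CID product-ion series
(c/y/w/a/a-B), and ppm-tolerant assignment of observed ions.

Mass model
----------
A residue contributes its nucleoside-3'-monophosphate mass minus water
(e.g. A = AMP - H2O = 329.05252 Da); each methyl (base or ribose) adds one
CH2 = 14.01565 Da. Terminal chemistry then fixes the neutral mass:

====================  =========================
5'-OH, 3'-P (or
5'-P, 3'-OH)          sum(residues) + H2O
5'-OH, 3'-OH          sum(residues) + H2O - HPO3
5'-OH, 3'-cyclicP     sum(residues)
5'-P,  3'-P           sum(residues) + H2O + HPO3
====================  =========================

This reproduces, e.g., the RNase T1 12-mer of human mitochondrial 16S rRNA
(positions 939-950, UUCCUUAA[m1A]UAGp): 3833.49 Da, [M-5H]5- at m/z 765.69.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .seq_core import (
    MOD_REGISTRY,
    ModRNASeq,
    SequenceError,
    parse_mod_string,
    render_mod_string,
)

# ---------------------------------------------------------------------------
# Monoisotopic constants (Da)
# ---------------------------------------------------------------------------

#: Internal residue masses: ribonucleoside monophosphate minus water.
RESIDUE_MASS: dict[str, float] = {
    "C": 305.04129,
    "U": 306.02530,
    "A": 329.05252,
    "G": 345.04744,
}

CH2 = 14.01565        #: methyl substitution (base methyl and 2'-O-methyl alike)
H2O = 18.010565
HPO3 = 79.966331
PROTON = 1.0072765    #: mass of H+ removed per negative charge

#: Neutral nucleobase masses (BH) used for a-B ion calculation.
BASE_MASS: dict[str, float] = {
    "A": 135.05450,
    "G": 151.04941,
    "C": 111.04326,
    "U": 112.02728,
    "m1A": 149.07015,
}

ION_SERIES = ("c", "y", "w", "a", "a-B")
_FIVE_PRIME_SERIES = frozenset({"c", "a", "a-B"})


def residue_mass(residue) -> float:
    """Monoisotopic mass contribution of one (possibly methylated) residue."""
    mass = RESIDUE_MASS[residue.base]
    if residue.base_mod is not None:
        mass += MOD_REGISTRY[residue.base_mod].mass_delta
    if residue.sugar_2ome:
        mass += CH2
    return mass


def oligo_mass(seq: ModRNASeq | str) -> float:
    """Neutral monoisotopic mass of a modified oligoribonucleotide in Da.

    Accepts a :class:`~mitomodkit.seq_core.ModRNASeq` or shorthand text
    (``"AAm1AUp"`` -> 1325.21).
    """
    if isinstance(seq, str):
        seq = parse_mod_string(seq)
    core = sum(residue_mass(r) for r in seq.residues)
    five, three = seq.five_prime, seq.three_prime
    if three == "cyclicP":
        extra = 0.0 if five == "OH" else HPO3
    elif (five, three) in (("OH", "P"), ("P", "OH")):
        extra = H2O
    elif (five, three) == ("OH", "OH"):
        extra = H2O - HPO3
    else:  # 5'-P, 3'-P
        extra = H2O + HPO3
    return core + extra


def mz(mass: float, charge: int, polarity: str = "negative") -> float:
    """m/z of a multiply deprotonated ion: (M - n*H+)/n in negative mode."""
    if mass <= 0:
        raise ValueError("mass must be positive")
    if charge < 1:
        raise ValueError("charge must be >= 1")
    if polarity != "negative":
        raise ValueError("only negative-mode ESI is modeled")
    value = (mass - charge * PROTON) / charge
    if value <= 0:
        raise ValueError(f"nonpositive m/z for mass {mass} at charge {charge}")
    return value


# ---------------------------------------------------------------------------
# Digestion
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Fragment:
    """One digestion product with its 1-based inclusive parent span."""

    seq: ModRNASeq
    parent_span: tuple[int, int]
    enzyme: str
    missed_cleavages: int = 0

    def __post_init__(self) -> None:
        start, end = self.parent_span
        if end - start + 1 != len(self.seq):
            raise SequenceError("parent span length must equal residue count")

    @property
    def shorthand(self) -> str:
        return render_mod_string(self.seq)

    @property
    def mass(self) -> float:
        return oligo_mass(self.seq)


#: Cleavage specificity: the enzyme cuts 3' of these bases, leaving a
#: 3'-phosphate product (via the 2',3'-cyclic intermediate); 2'-O-methylation
#: of the residue 5' of the scissile bond blocks cleavage.
ENZYME_SPECIFICITY: dict[str, frozenset[str]] = {
    "RNaseT1": frozenset("G"),
    "RNaseA": frozenset("CU"),
}


def digest(
    seq: ModRNASeq | str,
    enzyme: str,
    missed_cleavages: int = 0,
    product_three_prime: str = "P",
) -> list[Fragment]:
    """In-silico single-strand endonuclease digestion.

    RNase T1 cleaves 3' of guanosine, RNase A 3' of pyrimidines; a residue
    whose ribose carries a 2'-O-methyl cannot form the cyclic intermediate
    and is never cleaved after. Internal fragments get 5'-OH and, by default,
    a linear 3'-phosphate (``product_three_prime="cyclicP"`` for the cyclic
    form); terminal fragments keep the parent's own termini. With
    ``missed_cleavages=k``, unions of up to k+1 adjacent complete fragments
    are appended (flagged via ``missed_cleavages``).
    """
    if isinstance(seq, str):
        seq = parse_mod_string(seq)
    try:
        cut_after = ENZYME_SPECIFICITY[enzyme]
    except KeyError:
        raise ValueError(f"unknown enzyme {enzyme!r}; choose from {sorted(ENZYME_SPECIFICITY)}")
    if missed_cleavages < 0:
        raise ValueError("missed_cleavages must be >= 0")
    if product_three_prime not in ("P", "cyclicP"):
        raise ValueError("product_three_prime must be 'P' or 'cyclicP'")

    n = len(seq)
    # cut sites: after residue index i (0-based), i.e. between i and i+1
    cuts = [i for i in range(n - 1)
            if seq.residues[i].base in cut_after and not seq.residues[i].sugar_2ome]
    bounds = [0] + [c + 1 for c in cuts] + [n]

    def make(lo: int, hi: int, missed: int) -> Fragment:
        residues = seq.residues[lo:hi]
        five = seq.five_prime if lo == 0 else "OH"
        three = seq.three_prime if hi == n else product_three_prime
        frag_seq = ModRNASeq(residues=residues,
                             start_pos=seq.start_pos + lo,
                             parent_name=seq.parent_name,
                             five_prime=five, three_prime=three)
        return Fragment(seq=frag_seq,
                        parent_span=(seq.start_pos + lo, seq.start_pos + hi - 1),
                        enzyme=enzyme, missed_cleavages=missed)

    fragments = [make(bounds[i], bounds[i + 1], 0) for i in range(len(bounds) - 1)]
    for k in range(1, missed_cleavages + 1):
        for i in range(len(bounds) - 1 - k):
            fragments.append(make(bounds[i], bounds[i + 1 + k], k))
    return fragments


# ---------------------------------------------------------------------------
# CID product ions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IonSpec:
    """One CID product ion: series, index, charge, neutral mass and m/z."""

    series: str
    index: int
    charge: int
    neutral_mass: float
    mz: float

    @property
    def label(self) -> str:
        return f"{self.series}{self.index}^{self.charge}-"


def _prefix_mass(seq: ModRNASeq, i: int) -> float:
    return sum(residue_mass(r) for r in seq.residues[:i])


def _suffix_mass(seq: ModRNASeq, k: int) -> float:
    return sum(residue_mass(r) for r in seq.residues[-k:])


def cid_neutral(seq: ModRNASeq, series: str, index: int) -> float:
    """Neutral mass of one product ion of a CID-fragmented parent.

    5'-side series (for a 5'-OH parent): c_i = prefix + H2O (3'-phosphate
    retained), a_i = c_i - HPO3, (a-B)_i = a_i - BH of residue i. A 5'-P
    parent shifts all 5'-side series by +HPO3. 3'-side series: y_k keeps the
    parent's own 3' terminus (per the oligo_mass rules) with a free 5'-OH;
    w_k = y_k + HPO3 (5'-phosphate retained).
    """
    n = len(seq)
    if not 1 <= index <= n - 1:
        raise ValueError(f"ion index {index} out of range for length-{n} parent")
    if series in _FIVE_PRIME_SERIES:
        mass = _prefix_mass(seq, index) + H2O
        if seq.five_prime == "P":
            mass += HPO3
        if series in ("a", "a-B"):
            mass -= HPO3
        if series == "a-B":
            res = seq.residues[index - 1]
            key = res.base_mod if res.base_mod is not None else res.base
            mass -= BASE_MASS[key]
        return mass
    if series in ("y", "w"):
        sub = ModRNASeq(residues=list(seq.residues[-index:]),
                        five_prime="OH", three_prime=seq.three_prime)
        mass = oligo_mass(sub)
        if series == "w":
            mass += HPO3
        return mass
    raise ValueError(f"unknown ion series {series!r}; choose from {ION_SERIES}")


def cid_series(
    frag: Fragment | ModRNASeq | str,
    series: tuple[str, ...] = ("c", "y", "w"),
    max_charge: int = 2,
) -> list[IonSpec]:
    """Full CID product-ion table for a fragment.

    Defaults to the c/y/w series at charges 1..2, the series routinely
    assigned in negative-mode CID spectra of short oligoribonucleotides.
    """
    if isinstance(frag, Fragment):
        seq = frag.seq
    elif isinstance(frag, str):
        seq = parse_mod_string(frag)
    else:
        seq = frag
    if len(seq) < 2:
        raise SequenceError("CID requires a fragment of length >= 2")
    if max_charge < 1:
        raise ValueError("max_charge must be >= 1")
    ions = []
    for s in series:
        for i in range(1, len(seq)):
            neutral = cid_neutral(seq, s, i)
            for z in range(1, max_charge + 1):
                ions.append(IonSpec(series=s, index=i, charge=z,
                                    neutral_mass=neutral, mz=mz(neutral, z)))
    return ions


# ---------------------------------------------------------------------------
# Ion matching
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IonMatch:
    observed_mz: float
    observed_charge: int
    ion: IonSpec | None      # None when no candidate fell inside tolerance
    delta_ppm: float | None


def match_ions(
    observed: list[tuple[float, int]],
    candidates: list[IonSpec],
    tol_ppm: float = 20.0,
) -> list[IonMatch]:
    """Assign observed (m/z, charge) pairs to theoretical ions.

    Each observation is paired with the same-charge candidate minimizing
    the absolute ppm deviation, provided it is within ``tol_ppm``;
    otherwise the observation is reported unmatched.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    if not candidates:
        raise ValueError("empty candidate list")
    out = []
    for obs_mz, obs_z in observed:
        best, best_ppm = None, math.inf
        for cand in candidates:
            if cand.charge != obs_z:
                continue
            ppm = (obs_mz - cand.mz) / cand.mz * 1e6
            if abs(ppm) < abs(best_ppm):
                best, best_ppm = cand, ppm
        if best is not None and abs(best_ppm) <= tol_ppm:
            out.append(IonMatch(obs_mz, obs_z, best, best_ppm))
        else:
            out.append(IonMatch(obs_mz, obs_z, None, None))
    return out
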