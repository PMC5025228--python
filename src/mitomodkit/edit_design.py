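"""MAGE oligo design, template assembly, T7 run-off, and RFLP prediction.

Covers the in-silico side of engineering the bacterial orthologue of the
16S rRNA 947 site: design of 90-nt lagging-strand single-strand oligos with
terminal phosphorothioate protection, detection of the restriction site the
edit creates (MluCI/AATT), restriction-fragment length prediction for
genotyping digests, greedy overlap assembly of a T7 transcription template
from printed oligos, and prediction of the run-off transcript.
"""

from __future__ import annotations

from dataclasses import dataclass

from .seq_core import (
    DNA_BASES,
    ModRNASeq,
    SequenceError,
    reverse_complement,
    transcribe,
)

T7_PROMOTER = "TAATACGACTCACTATA"


@dataclass(frozen=True)
class MageOligo:
    """Single-strand MAGE editing oligo.

    ``target_offset`` is the 1-based position of the edited base within the
    oligo; ``thio_bonds`` are the internucleotide linkages (1-based, linkage
    i joins residues i and i+1) carrying phosphorothioate protection against
    exonucleases; ``edit`` is (ref_base, new_base) in gene-strand coordinates.
    """

    seq: str
    target_offset: int
    thio_bonds: frozenset[int]
    edit: tuple[str, str]

    def __post_init__(self) -> None:
        L = len(self.seq)
        if not self.thio_bonds <= {1, 2, L - 2, L - 1}:
            raise ValueError("phosphorothioate bonds must be at terminal linkages")


@dataclass(frozen=True)
class RestrictionEnzymeSpec:
    """Restriction enzyme recognition site with a 5'-overhang cut offset.

    ``cut_offset`` is the number of bases between the start of the
    recognition site and the cut point on the given strand (0 = cut
    immediately 5' of the site, the MluCI convention).
    """

    name: str
    recognition: str
    cut_offset: int = 0

    def __post_init__(self) -> None:
        if not self.recognition or any(c not in DNA_BASES for c in self.recognition):
            raise ValueError(f"recognition sequence must be ACGT, got {self.recognition!r}")


#: MluCI cuts ^AATT leaving a 5'-AATT overhang; the site is palindromic so
#: detection is strand-agnostic.
MLUCI = RestrictionEnzymeSpec("MluCI", "AATT", cut_offset=0)

ENZYME_REGISTRY: dict[str, RestrictionEnzymeSpec] = {"MluCI": MLUCI}


def design_mage_oligo(
    gene_strand: str,
    target_pos: int,
    new_base: str,
    length: int = 90,
    lagging: bool = True,
) -> MageOligo:
    """Design a single-base-edit MAGE oligo.

    The window is centred so the edited base sits at oligo offset
    ``length//2 + 1`` (46 for the default 90-mer). With ``lagging=True`` the
    oligo anneals to the lagging strand, i.e. it is the reverse complement
    of the gene-strand window (carrying the complement of ``new_base``).
    The two outermost linkages at each end are phosphorothioated.
    """
    gene = gene_strand.upper()
    if any(c not in DNA_BASES for c in gene):
        raise SequenceError("gene_strand must be a DNA string")
    new_base = new_base.upper()
    if new_base not in DNA_BASES:
        raise ValueError(f"invalid replacement base {new_base!r}")
    if not 1 <= target_pos <= len(gene):
        raise ValueError("target_pos outside the gene strand")
    ref_base = gene[target_pos - 1]
    if new_base == ref_base:
        raise ValueError(f"new_base equals the reference base {ref_base!r}")

    offset = length // 2 + 1  # 1-based position of the edit within the oligo
    if lagging:
        # oligo offset k maps to gene-window position length - k + 1
        window_edit_pos = length - offset + 1
    else:
        window_edit_pos = offset
    start = target_pos - window_edit_pos + 1  # 1-based gene start of the window
    if start < 1 or start + length - 1 > len(gene):
        raise ValueError("edit target too close to the sequence end for this oligo length")
    window = gene[start - 1: start - 1 + length]
    edited = window[: window_edit_pos - 1] + new_base + window[window_edit_pos:]
    oligo_seq = reverse_complement(edited) if lagging else edited
    return MageOligo(
        seq=oligo_seq,
        target_offset=offset,
        thio_bonds=frozenset({1, 2, length - 2, length - 1}),
        edit=(ref_base, new_base))


def find_sites(seq: str, enzyme: RestrictionEnzymeSpec) -> list[int]:
    """All 1-based (overlapping) start positions of the recognition site."""
    if not seq:
        raise SequenceError("empty sequence")
    s, site = seq.upper(), enzyme.recognition.upper()
    hits, i = [], s.find(site)
    while i != -1:
        hits.append(i + 1)
        i = s.find(site, i + 1)
    return hits


def predict_rflp(amplicon: str, enzyme: RestrictionEnzymeSpec) -> list[int]:
    """Restriction fragment lengths of a complete digest of ``amplicon``.

    Cut points sit ``cut_offset`` bases after each recognition-site start
    (0 for MluCI: cut immediately before AATT). Lengths always sum to the
    amplicon length; a site-free amplicon yields one full-length fragment.
    """
    if not amplicon:
        raise SequenceError("empty amplicon")
    n = len(amplicon)
    cuts = sorted({(start - 1) + enzyme.cut_offset for start in find_sites(amplicon, enzyme)})
    cuts = [c for c in cuts if 0 < c < n]
    bounds = [0] + cuts + [n]
    return [bounds[i + 1] - bounds[i] for i in range(len(bounds) - 1)]


class AssemblyError(ValueError):
    """Overlap assembly failed or was ambiguous."""


def _overlap(a: str, b: str, min_overlap: int) -> int:
    """Length of the longest exact suffix of ``a`` matching a prefix of ``b``."""
    best = 0
    for k in range(min_overlap, min(len(a), len(b)) + 1):
        if a.endswith(b[:k]):
            best = k
    return best


def assemble_overlap(oligos: list[str], min_overlap: int = 15) -> str:
    """Greedy exact suffix/prefix assembly of overlapping DNA oligos.

    Each oligo may enter in either orientation (the terminal primer of a
    transcription template is conventionally written as the reverse
    complement of the bottom strand, so it is flipped during assembly).
    Repeatedly merges the pair with the longest exact overlap of at least
    ``min_overlap``; a tie between incompatible merges, or a leftover
    unmergeable oligo, raises :class:`AssemblyError`. The result is the
    top (sense) strand and is invariant to input order.
    """
    if len(oligos) < 2:
        raise ValueError("need at least two oligos to assemble")
    frags = [o.upper() for o in oligos]
    for f in frags:
        if any(c not in DNA_BASES for c in f):
            raise SequenceError("oligos must be DNA strings")

    while len(frags) > 1:
        # Absorb fragments fully contained in another (either orientation) —
        # e.g. a terminal primer written as the reverse complement of a
        # longer oligo's end extends nothing but confirms the assembly.
        absorbed = set()
        for j in range(len(frags)):
            for i in range(len(frags)):
                if i == j or i in absorbed or j in absorbed:
                    continue
                if frags[j] in frags[i] or reverse_complement(frags[j]) in frags[i]:
                    absorbed.add(j)
        if absorbed:
            frags = [f for k, f in enumerate(frags) if k not in absorbed]
            if len(frags) == 1:
                break
        candidates = []  # (overlap, i, j, merged); proper extensions only
        for i in range(len(frags)):
            for j in range(len(frags)):
                if i == j:
                    continue
                for b in (frags[j], reverse_complement(frags[j])):
                    ov = _overlap(frags[i], b, min_overlap)
                    if min_overlap <= ov < min(len(frags[i]), len(b)):
                        candidates.append((ov, i, j, frags[i] + b[ov:]))
        if not candidates:
            raise AssemblyError(f"no exact overlap >= {min_overlap} among remaining fragments")
        best_ov = max(c[0] for c in candidates)
        best = [c for c in candidates if c[0] == best_ov]
        # distinct merge products at the same best overlap -> ambiguous
        if len({min(c[3], reverse_complement(c[3])) for c in best}) > 1:
            raise AssemblyError("ambiguous assembly: multiple incompatible best merges")
        _, i, j, merged = best[0]
        frags = [f for k, f in enumerate(frags) if k not in (i, j)] + [merged]

    result = frags[0]
    # Canonical orientation: the strand containing a T7 promoter (if any)
    # is reported as the top strand.
    if T7_PROMOTER not in result and T7_PROMOTER in reverse_complement(result):
        result = reverse_complement(result)
    return result


def t7_runoff(template_top: str, start_pos: int = 1, parent_name: str = "") -> ModRNASeq:
    """Predict the T7 RNA polymerase run-off transcript of a template.

    Requires the class III T7 promoter on the top strand; transcription
    initiates at the first G after the promoter (+1 must be G for efficient
    initiation) and runs to the template end. Returns an unmodified RNA
    whose residues can be annotated downstream (e.g. m1A at the 947 site).
    """
    top = template_top.upper()
    idx = top.find(T7_PROMOTER)
    if idx == -1:
        raise SequenceError("T7 promoter not found on the top strand")
    plus1 = idx + len(T7_PROMOTER)
    if plus1 >= len(top) or top[plus1] != "G":
        raise SequenceError("transcription start (+1) base after the promoter must be G")
    rna = transcribe(top[plus1:])
    return ModRNASeq.from_bases(rna, start_pos=start_pos, parent_name=parent_name)
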