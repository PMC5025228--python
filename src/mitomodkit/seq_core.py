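"""Sequence data model shared by all mitomodkit modules.

Represents RNA/DNA sequences with per-residue modification annotations
(base methylation such as m1A, and 2'-O-ribose methylation), terminal
chemistry (5'/3' hydroxyl, phosphate, 2',3'-cyclic phosphate), and 1-based
coordinates in a named parent system (e.g. "human 16S rRNA", where the
mtDNA offset of the 16S gene maps rRNA position 947 to mtDNA 2617).

Conventions enforced package-wide:

* all coordinates are 1-based inclusive;
* RNA and DNA alphabets are distinct — ``transcribe``/``reverse_transcribe``
  are the only T<->U conversions;
* modified sequences round-trip exactly through the shorthand notation
  (``m1`` prefix = base methyl, ``m`` suffix = 2'-O-methyl, trailing ``p`` =
  3'-phosphate, trailing ``>p`` = 2',3'-cyclic phosphate).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

RNA_BASES = frozenset("ACGU")
DNA_BASES = frozenset("ACGT")

FIVE_PRIME_STATES = ("OH", "P")
THREE_PRIME_STATES = ("OH", "P", "cyclicP")

#: IUPAC nucleotide codes, RNA-normalized (T is folded into U on lookup).
IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "U": frozenset("U"), "T": frozenset("U"),
    "R": frozenset("AG"), "Y": frozenset("CU"), "S": frozenset("CG"),
    "W": frozenset("AU"), "K": frozenset("GU"), "M": frozenset("AC"),
    "B": frozenset("CGU"), "D": frozenset("AGU"), "H": frozenset("ACU"),
    "V": frozenset("ACG"), "N": frozenset("ACGU"),
}


class SequenceError(ValueError):
    """Invalid sequence, modification, or coordinate input."""


@dataclass(frozen=True)
class ModSpec:
    """Registry entry for a base modification.

    ``mass_delta`` is the monoisotopic shift in Da relative to the
    unmodified residue; ``base`` constrains which nucleobase may carry it.
    """

    label: str
    base: str
    mass_delta: float
    prefix: str  # shorthand prefix written before the base letter


# Base-modification registry. Extensible at run time via register_modification
# (e.g. from a CLI config); ships with m1A, the mark this package was built for.
MOD_REGISTRY: dict[str, ModSpec] = {}


def register_modification(label: str, base: str, mass_delta: float, prefix: str | None = None) -> ModSpec:
    if base not in RNA_BASES:
        raise SequenceError(f"modification base constraint must be an RNA base, got {base!r}")
    spec = ModSpec(label=label, base=base, mass_delta=mass_delta,
                   prefix=prefix if prefix is not None else label[: -len(base)])
    MOD_REGISTRY[label] = spec
    return spec


register_modification("m1A", "A", 14.01565, prefix="m1")


@dataclass(frozen=True)
class ModResidue:
    """One RNA residue with optional base and sugar methylation."""

    base: str
    base_mod: str | None = None
    sugar_2ome: bool = False

    def __post_init__(self) -> None:
        if self.base not in RNA_BASES:
            raise SequenceError(f"invalid RNA base {self.base!r}")
        if self.base_mod is not None:
            spec = MOD_REGISTRY.get(self.base_mod)
            if spec is None:
                raise SequenceError(f"unknown modification label {self.base_mod!r}")
            if spec.base != self.base:
                raise SequenceError(
                    f"modification {self.base_mod} requires base {spec.base}, got {self.base}")

    @property
    def n_methyl(self) -> int:
        """Number of methyl groups on this residue (base + sugar)."""
        return int(self.base_mod is not None) + int(self.sugar_2ome)


@dataclass
class ModRNASeq:
    """Ordered modified-RNA sequence anchored in a parent coordinate system.

    ``start_pos`` is the 1-based parent position of the first residue;
    residue i (1-based) sits at parent position ``start_pos + i - 1``.
    """

    residues: list[ModResidue]
    start_pos: int = 1
    parent_name: str = ""
    five_prime: str = "OH"
    three_prime: str = "OH"

    def __post_init__(self) -> None:
        if not self.residues:
            raise SequenceError("sequence must contain at least one residue")
        if self.start_pos < 1:
            raise SequenceError("start_pos must be >= 1 (coordinates are 1-based)")
        if self.five_prime not in FIVE_PRIME_STATES:
            raise SequenceError(f"invalid 5' terminus {self.five_prime!r}")
        if self.three_prime not in THREE_PRIME_STATES:
            raise SequenceError(f"invalid 3' terminus {self.three_prime!r}")

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self) -> Iterator[ModResidue]:
        return iter(self.residues)

    @property
    def bases(self) -> str:
        """Plain base string without modification annotations."""
        return "".join(r.base for r in self.residues)

    @property
    def end_pos(self) -> int:
        return self.start_pos + len(self.residues) - 1

    @property
    def span(self) -> tuple[int, int]:
        """1-based inclusive parent span."""
        return (self.start_pos, self.end_pos)

    def residue_at(self, parent_pos: int) -> ModResidue:
        if not self.start_pos <= parent_pos <= self.end_pos:
            raise SequenceError(f"parent position {parent_pos} outside span {self.span}")
        return self.residues[parent_pos - self.start_pos]

    def with_modification(self, parent_pos: int, label: str) -> "ModRNASeq":
        """Return a copy carrying base modification ``label`` at ``parent_pos``."""
        idx = parent_pos - self.start_pos
        if not 0 <= idx < len(self.residues):
            raise SequenceError(f"parent position {parent_pos} outside span {self.span}")
        residues = list(self.residues)
        residues[idx] = replace(residues[idx], base_mod=label)
        return replace(self, residues=residues)

    def subseq(self, start: int, end: int) -> "ModRNASeq":
        """Sub-sequence by 1-based inclusive parent positions, termini reset to OH."""
        if not (self.start_pos <= start <= end <= self.end_pos):
            raise SequenceError(f"span ({start}, {end}) outside parent span {self.span}")
        return ModRNASeq(
            residues=self.residues[start - self.start_pos: end - self.start_pos + 1],
            start_pos=start, parent_name=self.parent_name,
            five_prime="OH", three_prime="OH")

    def to_json(self) -> str:
        return json.dumps({
            "residues": [
                {"base": r.base, "base_mod": r.base_mod, "sugar_2ome": r.sugar_2ome}
                for r in self.residues],
            "start_pos": self.start_pos,
            "parent_name": self.parent_name,
            "five_prime": self.five_prime,
            "three_prime": self.three_prime,
        })

    @classmethod
    def from_json(cls, text: str) -> "ModRNASeq":
        d = json.loads(text)
        return cls(
            residues=[ModResidue(**r) for r in d["residues"]],
            start_pos=d["start_pos"], parent_name=d["parent_name"],
            five_prime=d["five_prime"], three_prime=d["three_prime"])

    @classmethod
    def from_bases(cls, bases: str, **kwargs) -> "ModRNASeq":
        return cls(residues=[ModResidue(b) for b in bases.upper()], **kwargs)


@dataclass(frozen=True)
class CoordinateMap:
    """Affine 1-based coordinate map: parent_pos = local_pos + offset."""

    name: str
    offset: int

    def to_parent(self, local_pos: int) -> int:
        return map_coordinate(local_pos, self)

    def to_local(self, parent_pos: int) -> int:
        local = parent_pos - self.offset
        if local < 1:
            raise SequenceError(f"mapped local position {local} < 1")
        return local


#: Human mitochondrial 16S rRNA local coordinates to mtDNA (rCRS) coordinates;
#: 16S position 947 maps to mtDNA 2617.
HUMAN_16S_TO_MTDNA = CoordinateMap("human 16S rRNA -> mtDNA", offset=1670)


def map_coordinate(pos: int, cmap: CoordinateMap) -> int:
    """Map a 1-based local position into 1-based parent coordinates."""
    if pos < 1:
        raise SequenceError("positions are 1-based; pos must be >= 1")
    parent = pos + cmap.offset
    if parent < 1:
        raise SequenceError(f"mapped parent position {parent} < 1")
    return parent


# ---------------------------------------------------------------------------
# Modified-sequence shorthand
# ---------------------------------------------------------------------------

def parse_mod_string(text: str) -> ModRNASeq:
    """Parse modified-RNA shorthand into a :class:`ModRNASeq`.

    Grammar: a run of residue tokens followed by an optional 3'-terminus
    marker. A residue token is ``[<mod-prefix>]<base>[m]`` where a registered
    modification prefix (``m1`` for m1A) marks the base, and a trailing ``m``
    not followed by a digit marks 2'-O-ribose methylation. The suffix ``p``
    denotes a 3'-phosphate, ``>p`` a 2',3'-cyclic phosphate; with no suffix
    both termini default to hydroxyl.

    >>> s = parse_mod_string("UUCCUUAAm1AUAGp")
    >>> len(s), s.residues[8].base_mod, s.three_prime
    (12, 'm1A', 'P')
    """
    if not text:
        raise SequenceError("empty sequence string")
    body = text
    three_prime = "OH"
    if body.endswith(">p"):
        body, three_prime = body[:-2], "cyclicP"
    elif body.endswith("p"):
        body, three_prime = body[:-1], "P"
    if not body:
        raise SequenceError(f"no residues in {text!r}")

    prefixes = sorted({s.prefix for s in MOD_REGISTRY.values()}, key=len, reverse=True)
    residues: list[ModResidue] = []
    i = 0
    while i < len(body):
        base_mod = None
        for pfx in prefixes:
            if body.startswith(pfx, i):
                rest = body[i + len(pfx):]
                if not rest:
                    raise SequenceError(f"dangling modification prefix in {text!r}")
                matches = [lbl for lbl, s in MOD_REGISTRY.items()
                           if s.prefix == pfx and s.base == rest[0]]
                if not matches:
                    raise SequenceError(
                        f"modification prefix {pfx!r} not registered for base {rest[0]!r}")
                base_mod = matches[0]
                i += len(pfx)
                break
        base = body[i]
        if base not in RNA_BASES:
            raise SequenceError(f"invalid base {base!r} at position {i + 1} of {text!r}")
        i += 1
        sugar = False
        # 'm' is a sugar-methyl suffix only when not opening a mod prefix
        # (e.g. the 'm1' in ...Am1A belongs to the following residue).
        if i < len(body) and body[i] == "m" and not any(
                body.startswith(pfx, i) and i + len(pfx) < len(body) and
                body[i + len(pfx)] in RNA_BASES for pfx in prefixes):
            sugar = True
            i += 1
        residues.append(ModResidue(base=base, base_mod=base_mod, sugar_2ome=sugar))
    return ModRNASeq(residues=residues, three_prime=three_prime)


def render_mod_string(seq: ModRNASeq) -> str:
    """Inverse of :func:`parse_mod_string` (exact round-trip)."""
    parts = []
    for r in seq.residues:
        if r.base_mod is not None:
            parts.append(MOD_REGISTRY[r.base_mod].prefix)
        parts.append(r.base)
        if r.sugar_2ome:
            parts.append("m")
    if seq.three_prime == "P":
        parts.append("p")
    elif seq.three_prime == "cyclicP":
        parts.append(">p")
    return "".join(parts)


# ---------------------------------------------------------------------------
# Motif scanning and alphabet conversion
# ---------------------------------------------------------------------------

def iupac_scan(seq: str, motif: str) -> list[int]:
    """All 1-based start positions where ``motif`` (IUPAC codes) matches ``seq``.

    U and T are treated as equivalent on both sides, so the same motif
    (e.g. the YMRAW methyltransferase consensus) scans RNA and DNA alike.
    """
    if not motif:
        raise SequenceError("empty motif")
    try:
        sets = [IUPAC_CODES[c] for c in motif.upper()]
    except KeyError as exc:
        raise SequenceError(f"invalid IUPAC code {exc.args[0]!r}") from None
    s = seq.upper().replace("T", "U")
    if any(c not in RNA_BASES for c in s):
        raise SequenceError("sequence contains non-ACGT/U characters")
    n, m = len(s), len(sets)
    return [i + 1 for i in range(n - m + 1)
            if all(s[i + j] in sets[j] for j in range(m))]


_DNA_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def reverse_complement(dna: str) -> str:
    """Reverse complement of a DNA string (case preserved)."""
    if any(c not in DNA_BASES for c in dna.upper()):
        raise SequenceError("reverse_complement expects a DNA string")
    return dna.translate(_DNA_COMPLEMENT)[::-1]


def transcribe(dna: str) -> str:
    """DNA coding strand -> RNA (T->U); the only sanctioned alphabet crossing."""
    if any(c not in DNA_BASES for c in dna.upper()):
        raise SequenceError("transcribe expects a DNA string")
    return dna.upper().replace("T", "U")


def reverse_transcribe(rna: str) -> str:
    """RNA -> DNA coding strand (U->T)."""
    if any(c not in RNA_BASES for c in rna.upper()):
        raise SequenceError("reverse_transcribe expects an RNA string")
    return rna.upper().replace("U", "T")


# ---------------------------------------------------------------------------
# FASTA I/O (Biopython-backed)
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    """Read a multi-record FASTA into an ordered {name: sequence} dict."""
    records = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not records:
        raise SequenceError(f"no FASTA records in {path}")
    return records


def write_fasta(path, records: dict[str, str] | Iterable[tuple[str, str]], width: int = 70) -> None:
    items = records.items() if isinstance(records, dict) else records
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in items]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)
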