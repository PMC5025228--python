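"""RNA-DNA-difference (RDD) calling with an m1A misincorporation signature.

m1A blocks Watson-Crick pairing, so reverse transcriptase either
misincorporates (reads show T or G at the A site) or arrests (local coverage
dip). This module builds quality- and edge-filtered per-strand pileups from
aligned reads, applies the two-stage RDD filter (coverage filter A: >= 1000
high-quality reads; strand-aware fraction filter B: secondary base >= 1.6%
of total coverage and >= 0.8% of each strand's reads), flags read-edge
artifacts, scores the m1A signature (mismatch rate + coverage drop), and
compares modification levels between samples with a Pearson chi-square test.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field

import pysam
from scipy import stats

from .seq_core import read_fasta

STRANDS = ("+", "-")
BASES = ("A", "C", "G", "T")


@dataclass
class PileupColumn:
    """Per-position, per-strand, per-base counts of quality-passing calls."""

    ref_name: str
    pos: int                       # 1-based
    ref_base: str
    counts: dict[tuple[str, str], int] = field(default_factory=dict)  # (base, strand) -> n
    deletions: int = 0             # excluded from counts, reported separately
    other: int = 0                 # Ns and non-ACGT calls

    def count(self, base: str, strand: str | None = None) -> int:
        if strand is None:
            return sum(self.counts.get((base, s), 0) for s in STRANDS)
        return self.counts.get((base, strand), 0)

    @property
    def coverage(self) -> int:
        return sum(self.counts.values())

    def strand_coverage(self, strand: str) -> int:
        return sum(v for (b, s), v in self.counts.items() if s == strand)

    @property
    def freq(self) -> dict[str, float]:
        cov = self.coverage
        if cov == 0:
            raise ValueError(f"zero coverage at {self.ref_name}:{self.pos}")
        return {b: self.count(b) / cov for b in BASES}


def build_pileup(
    alignments,
    reference,
    min_base_q: int = 30,
    min_mapq: int = 20,
    edge_trim: int = 5,
) -> list[PileupColumn]:
    """Quality-filtered per-strand pileup from a SAM/BAM file.

    ``reference`` may be a FASTA path or a {name: sequence} dict. Base calls
    with quality < ``min_base_q``, reads with MAPQ < ``min_mapq``, and calls
    within ``edge_trim`` positions of either read end are excluded; deletions
    and N calls are tallied separately. Coordinates in the output are 1-based.
    """
    refs = reference if isinstance(reference, dict) else read_fasta(reference)
    columns: dict[tuple[str, int], PileupColumn] = {}

    with pysam.AlignmentFile(str(alignments), check_sq=False) as sam:
        for read in sam:
            if read.is_unmapped or read.is_secondary or read.is_supplementary or read.is_duplicate:
                continue
            if (read.mapping_quality or 0) < min_mapq:
                continue
            rname = read.reference_name
            if rname not in refs:
                raise ValueError(f"read {read.query_name} aligned to {rname!r}, "
                                 f"absent from the reference FASTA")
            ref_seq = refs[rname]
            seq = read.query_sequence
            quals = read.query_qualities
            qlen = len(seq)
            strand = "-" if read.is_reverse else "+"
            for qpos, rpos in read.get_aligned_pairs():
                if rpos is None:
                    continue  # insertion relative to reference
                key = (rname, rpos + 1)
                col = columns.get(key)
                if col is None:
                    if rpos >= len(ref_seq):
                        raise ValueError(f"alignment past end of reference {rname}")
                    col = columns[key] = PileupColumn(
                        ref_name=rname, pos=rpos + 1, ref_base=ref_seq[rpos])
                if qpos is None:
                    col.deletions += 1
                    continue
                if qpos < edge_trim or qpos >= qlen - edge_trim:
                    continue
                if quals is not None and quals[qpos] < min_base_q:
                    continue
                base = seq[qpos].upper()
                if base not in BASES:
                    col.other += 1
                    continue
                col.counts[(base, strand)] = col.counts.get((base, strand), 0) + 1
    return [columns[k] for k in sorted(columns)]


@dataclass
class RDDCall:
    """Filter verdicts and allele fractions for one site."""

    ref_name: str
    pos: int
    ref_base: str
    coverage: int
    freq: dict[str, float]
    secondary_base: str | None
    secondary_fraction_total: float
    secondary_fraction_by_strand: tuple[float, float]  # (+, -), per-strand denominators
    pass_filter_A: bool
    pass_filter_B: bool
    edge_bias_flag: bool
    rdd_level: float

    @property
    def is_rdd(self) -> bool:
        return self.pass_filter_A and self.pass_filter_B and not self.edge_bias_flag


def call_rdd(
    columns: list[PileupColumn],
    min_coverage: int = 1000,
    min_total_fraction: float = 0.016,
    min_strand_fraction: float = 0.008,
    edge_flags: dict[int, bool] | None = None,
    waive_coverage_filter: bool = False,
) -> list[RDDCall]:
    """Apply the RDD filters to pileup columns.

    Filter A: coverage >= ``min_coverage`` high-quality calls (waivable per
    sample, e.g. for shallow datasets, via ``waive_coverage_filter``).
    Filter B: the strongest non-reference base must reach
    ``min_total_fraction`` of total coverage AND ``min_strand_fraction`` of
    the reads of each strand. ``edge_flags`` (pos -> bool) carries
    :func:`edge_bias_test` verdicts; a site is an RDD call iff both filters
    pass and it is not edge-flagged.
    """
    edge_flags = edge_flags or {}
    calls = []
    for col in columns:
        cov = col.coverage
        if cov == 0:
            continue
        freq = col.freq
        non_ref = [(col.count(b), b) for b in BASES if b != col.ref_base]
        best_count, secondary = max(non_ref)
        if best_count == 0:
            secondary = None
        frac_total = best_count / cov
        strand_fracs = []
        for s in STRANDS:
            scov = col.strand_coverage(s)
            strand_fracs.append(
                (col.count(secondary, s) / scov) if secondary and scov else 0.0)
        pass_a = waive_coverage_filter or cov >= min_coverage
        pass_b = (secondary is not None
                  and frac_total >= min_total_fraction
                  and all(f >= min_strand_fraction for f in strand_fracs))
        calls.append(RDDCall(
            ref_name=col.ref_name, pos=col.pos, ref_base=col.ref_base,
            coverage=cov, freq=freq, secondary_base=secondary,
            secondary_fraction_total=frac_total,
            secondary_fraction_by_strand=(strand_fracs[0], strand_fracs[1]),
            pass_filter_A=pass_a, pass_filter_B=pass_b,
            edge_bias_flag=bool(edge_flags.get(col.pos, False)),
            rdd_level=1.0 - freq[col.ref_base]))
    return calls


def edge_bias_test(
    variant_read_offsets: list[int],
    read_length: int,
    window: int = 5,
    alpha: float = 0.01,
) -> tuple[bool, float]:
    """One-sided binomial test for variant calls piling up at read edges.

    ``variant_read_offsets`` are distances of each variant call from the
    nearer read end. Under the null (variants uniform along the read) the
    probability that a call lies within ``window`` of an end is
    2*window/read_length; an excess flags the site as an edge artifact.
    Returns ``(flag, p)``; with zero variant calls the flag is False, p = 1.
    """
    if window >= read_length / 2:
        raise ValueError("window must be < read_length/2")
    if any(o < 0 or o > read_length / 2 for o in variant_read_offsets):
        raise ValueError("offsets must lie in [0, read_length/2]")
    n = len(variant_read_offsets)
    if n == 0:
        return False, 1.0
    k = sum(1 for o in variant_read_offsets if o < window)
    p0 = 2 * window / read_length
    p = stats.binomtest(k, n, p0, alternative="greater").pvalue
    return p < alpha, float(p)


@dataclass
class SignatureScore:
    """Components of the m1A signature at an adenosine site."""

    pos: int
    mismatch_rate: float      # freq(T) + freq(G) at the A reference site
    coverage_drop: float      # 1 - cov(site)/median(flank coverage), floored at 0
    combined: float           # sum of the two components, in [0, 2]


def m1a_signature(columns: list[PileupColumn], site: int, flank: int = 25) -> SignatureScore:
    """Score the m1A RT signature: misincorporation plus local coverage dip.

    The flank median is taken over covered positions in
    [site - flank, site + flank] excluding the site itself.
    """
    if flank < 10:
        raise ValueError("flank must be >= 10")
    by_pos = {c.pos: c for c in columns}
    col = by_pos.get(site)
    if col is None or col.coverage == 0:
        raise ValueError(f"no coverage at site {site}")
    if col.ref_base != "A":
        raise ValueError(f"site {site} reference base is {col.ref_base}, expected A")
    freq = col.freq
    mismatch = freq["T"] + freq["G"]
    flank_cov = [by_pos[p].coverage for p in range(site - flank, site + flank + 1)
                 if p != site and p in by_pos and by_pos[p].coverage > 0]
    if len(flank_cov) < flank:
        raise ValueError(f"insufficient flank coverage around site {site}")
    med = statistics.median(flank_cov)
    drop = max(0.0, 1.0 - col.coverage / med)
    return SignatureScore(pos=site, mismatch_rate=mismatch,
                          coverage_drop=drop, combined=mismatch + drop)


def compare_samples(
    counts_a: tuple[int, int],
    counts_b: tuple[int, int],
) -> tuple[float, float]:
    """Pearson chi-square comparison of modification levels in two samples.

    Inputs are (modified, unmodified) read counts, where "modified" is the
    non-reference count at the site. Returns the uncorrected Pearson
    statistic (1 df) and its p-value; when any expected cell is < 5 the
    p-value falls back to Fisher's exact test (the statistic is still the
    Pearson value).
    """
    a_mod, a_un = counts_a
    b_mod, b_un = counts_b
    if min(a_mod, a_un, b_mod, b_un) < 0:
        raise ValueError("counts must be non-negative")
    n = a_mod + a_un + b_mod + b_un
    row1, row2 = a_mod + a_un, b_mod + b_un
    col1, col2 = a_mod + b_mod, a_un + b_un
    if 0 in (row1, row2, col1, col2):
        raise ValueError("chi-square undefined: a table margin is zero")
    chi2 = n * (a_mod * b_un - a_un * b_mod) ** 2 / (row1 * row2 * col1 * col2)
    expected_min = min(r * c / n for r in (row1, row2) for c in (col1, col2))
    if expected_min < 5:
        p = stats.fisher_exact([[a_mod, a_un], [b_mod, b_un]])[1]
    else:
        p = stats.chi2.sf(chi2, df=1)
    return float(chi2), float(p)


def frequency_table(column: PileupColumn) -> dict[str, float]:
    """Per-base percentages of total coverage (strands pooled)."""
    cov = column.coverage
    if cov == 0:
        raise ValueError(f"zero coverage at {column.ref_name}:{column.pos}")
    return {b: 100.0 * column.count(b) / cov for b in BASES}
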