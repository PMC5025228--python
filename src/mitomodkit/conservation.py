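"""Cross-species anchoring of the 16S rRNA 947 site and genotype/RDD tables.

The modified adenosine of human mitochondrial 16S rRNA (position 947; mtDNA
2617) is conserved across vertebrates. To test another species, the human
window around the site is locally aligned against that species' mtDNA and
the column aligned to the window centre gives the orthologous position.
Genotype (A vs T in mtDNA) is then tabulated against RDD presence in the
species' RNA pileup.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from Bio import Align

from .rdd_caller import PileupColumn, call_rdd
from .seq_core import read_fasta

MATCH_SCORE = 2
MISMATCH_SCORE = -1
GAP_SCORE = -2          # linear gap penalty (no affine extension)
MIN_SCORE_FRACTION = 0.6


class AnchorError(ValueError):
    """Ortholog anchoring failed (low identity or ambiguous placement)."""


@dataclass(frozen=True)
class OrthologAnchor:
    species: str
    target_pos: int          # 1-based position in the target mtDNA
    alignment_score: float
    window: tuple[int, int]  # 1-based human span used as query


def _as_sequence(source) -> str:
    if isinstance(source, str) and set(source.upper()) <= set("ACGTN"):
        return source.upper()
    records = read_fasta(source)
    return next(iter(records.values()))


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = MATCH_SCORE
    aligner.mismatch_score = MISMATCH_SCORE
    aligner.open_gap_score = GAP_SCORE
    aligner.extend_gap_score = GAP_SCORE
    return aligner


def map_ortholog(
    human_mtdna,
    target_mtdna,
    human_pos: int = 2617,
    window: int = 30,
    species: str = "",
) -> OrthologAnchor:
    """Locate the target-species position orthologous to a human mtDNA site.

    Extracts the human window ``human_pos ± window`` (so 2*window+1 nt) and
    aligns it locally (match +2, mismatch -1, linear gap -2) against the
    target. The anchor is the target column aligned to the window centre.
    Fails if the best score is below 60% of the maximum attainable, if the
    centre falls in a gap, or if two co-optimal alignments disagree on the
    anchor. Inputs may be FASTA paths or raw sequence strings.
    """
    if window < 15:
        raise ValueError("window must be >= 15")
    human = _as_sequence(human_mtdna)
    target = _as_sequence(target_mtdna)
    lo, hi = human_pos - window, human_pos + window
    if lo < 1 or hi > len(human):
        raise ValueError(f"window {lo}-{hi} outside the human sequence")
    query = human[lo - 1: hi]
    centre = window  # 0-based index of the site within the query

    aligner = _make_aligner()
    alignments = aligner.align(query, target)
    best = alignments[0]
    max_score = MATCH_SCORE * len(query)
    if best.score < MIN_SCORE_FRACTION * max_score:
        raise AnchorError(
            f"best local alignment score {best.score} below "
            f"{MIN_SCORE_FRACTION:.0%} of maximum {max_score}")

    def anchor_of(alignment) -> int | None:
        for (q0, q1), (t0, t1) in zip(alignment.aligned[0], alignment.aligned[1]):
            if q0 <= centre < q1:
                return t0 + (centre - q0) + 1  # 1-based
        return None

    pos = anchor_of(best)
    if pos is None:
        raise AnchorError("window centre falls in an alignment gap")
    # Co-optimal check: a second optimal alignment placing the centre
    # elsewhere makes the anchor ambiguous.
    try:
        second = alignments[1]
    except IndexError:
        second = None
    if second is not None and second.score == best.score:
        other = anchor_of(second)
        if other is not None and other != pos:
            raise AnchorError(f"ambiguous anchor: co-optimal placements {pos} and {other}")
    return OrthologAnchor(species=species, target_pos=pos,
                          alignment_score=float(best.score), window=(lo, hi))


@dataclass
class SpeciesPanelEntry:
    """One species' evidence: genotype base, RNA pileup, anchored site."""

    species: str
    mtdna_base: str            # DNA-derived base at the anchored position
    columns: list[PileupColumn]
    site: int                  # anchored 1-based position in this species' mtDNA
    waive_coverage_filter: bool = False


def genotype_rdd_table(
    panel: list[SpeciesPanelEntry],
    min_coverage: int = 1000,
    min_total_fraction: float = 0.016,
    min_strand_fraction: float = 0.008,
) -> pd.DataFrame:
    """Tabulate mtDNA genotype against RDD presence per species.

    RDD presence is the full filter-A/B verdict of the RDD caller at the
    anchored site. Rows are sorted by species name, so the table is
    invariant to input order.
    """
    rows = []
    for entry in panel:
        site_cols = [c for c in entry.columns if c.pos == entry.site]
        if not site_cols:
            raise ValueError(f"no pileup column at anchored site {entry.site} "
                             f"for species {entry.species}")
        calls = call_rdd(site_cols, min_coverage=min_coverage,
                         min_total_fraction=min_total_fraction,
                         min_strand_fraction=min_strand_fraction,
                         waive_coverage_filter=entry.waive_coverage_filter)
        call = calls[0]
        rows.append({
            "species": entry.species,
            "mtdna_base": entry.mtdna_base,
            "site": entry.site,
            "coverage": call.coverage,
            "secondary_fraction": call.secondary_fraction_total,
            "rdd_present": call.is_rdd,
        })
    return (pd.DataFrame(rows)
            .sort_values("species", kind="stable")
            .reset_index(drop=True))
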